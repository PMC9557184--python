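"""Model evaluation reports: metrics, ROC comparisons, risk-group survival."""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError
from .fusion import FusedModel
from .metrics import (
    SurvivalRecord,
    confusion_metrics,
    delong_test,
    kaplan_meier,
    logrank_test,
    roc_auc,
)

__all__ = ["evaluate_model"]


def _metric_block(probs: np.ndarray, labels: np.ndarray, threshold: float) -> dict:
    sens, spec, acc = confusion_metrics(probs, labels, threshold)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "auc": roc_auc(probs, labels),
    }


def evaluate_model(
    model: FusedModel,
    tables: dict,
    survival: list[SurvivalRecord] | None = None,
    threshold: float = 0.5,
) -> dict:
    """Evaluate a fused model on validation tables.

    ``tables`` maps modality -> FeatureTable with consistent patient order.
    The report holds per-modality and fused confusion metrics and AUC, a
    DeLong comparison of each modality's ROC against the fused one, and —
    when survival records are given (same patient order) — Kaplan-Meier
    curves plus a log-rank test for the predicted risk groups.
    """
    if set(tables) != set(model.models):
        raise InvalidArgumentError("validation tables must cover the model's modalities")
    ids = None
    labels = None
    for mod, t in tables.items():
        if ids is None:
            ids, labels = t.patient_ids, t.labels
        elif t.patient_ids != ids:
            raise InvalidArgumentError("patient ids differ between modality tables")
    rows = {mod: t.values for mod, t in tables.items()}

    per_mod = model.modality_probs(rows)
    fused = model.predict_fused(rows)
    report: dict = {
        "threshold": threshold,
        "n_patients": len(labels),
        "modalities": {},
        "fused": _metric_block(fused, labels, threshold),
    }
    for k, mod in enumerate(model.modalities):
        block = _metric_block(per_mod[k], labels, threshold)
        _, _, z, p = delong_test(per_mod[k], fused, labels)
        block["delong_vs_fused"] = {"z": z, "p": p}
        report["modalities"][mod] = block

    if survival is not None:
        if len(survival) != len(labels):
            raise InvalidArgumentError("one survival record per patient required")
        risk = fused >= threshold
        groups = {}
        for name, sel in (("low_risk", ~risk), ("high_risk", risk)):
            recs = [r for r, s in zip(survival, sel) if s]
            groups[name] = {
                "n": len(recs),
                "km": kaplan_meier(recs).to_frame().to_dict("list") if recs else None,
            }
        if groups["low_risk"]["n"] and groups["high_risk"]["n"]:
            chi2, p = logrank_test(
                [r for r, s in zip(survival, ~risk) if s],
                [r for r, s in zip(survival, risk) if s],
            )
            groups["logrank"] = {"chi2": chi2, "p": p}
        else:
            groups["logrank"] = None
        report["risk_groups"] = groups
    return report
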