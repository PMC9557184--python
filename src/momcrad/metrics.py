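"""Evaluation battery: confusion metrics, ROC/AUC, DeLong, Kaplan-Meier, log-rank.

AUC is the Mann-Whitney statistic (ties count 0.5), computed from midranks;
the DeLong test compares two correlated AUCs through placement-value
covariances with a two-sided normal p-value.  Survival estimation and the
log-rank test are delegated to lifelines behind this module's surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import norm, rankdata

from .errors import InvalidArgumentError

__all__ = [
    "SurvivalRecord",
    "confusion_metrics",
    "roc_auc",
    "delong_test",
    "kaplan_meier",
    "KMCurve",
    "logrank_test",
]


@dataclass
class SurvivalRecord:
    """Time (months) to local persistence/recurrence or last follow-up."""

    patient_id: str
    time: float
    event: int  # 1 = local P/R observed, 0 = censored

    def __post_init__(self) -> None:
        if not (np.isfinite(self.time) and self.time > 0):
            raise InvalidArgumentError("survival time must be positive")
        if self.event not in (0, 1):
            raise InvalidArgumentError("event flag must be 0 or 1")


def _check_two_class(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if not ((labels == 1).any() and (labels == 0).any()):
        raise InvalidArgumentError("both outcome classes must be present")
    return labels


def confusion_metrics(
    probabilities, labels, threshold: float = 0.5
) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) at a probability threshold.

    p >= threshold predicts positive (inclusive boundary).
    """
    p = np.asarray(probabilities, dtype=float)
    y = _check_two_class(labels)
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / len(y)
    return sens, spec, acc


def roc_auc(probabilities, labels) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    p = np.asarray(probabilities, dtype=float)
    y = _check_two_class(labels)
    n_pos = int((y == 1).sum())
    n_neg = len(y) - n_pos
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return v10, v01, auc


def delong_test(probs_a, probs_b, labels) -> tuple[float, float, float, float]:
    """DeLong comparison of two correlated AUCs on the same samples.

    Returns (auc_a, auc_b, z, two-sided p).  With identical scores the
    variance of the AUC difference is 0 and (z, p) = (0, 1).
    """
    y = _check_two_class(labels)
    a = np.asarray(probs_a, dtype=float)
    b = np.asarray(probs_b, dtype=float)
    if a.shape != b.shape or a.shape != y.shape:
        raise InvalidArgumentError("paired scores must match the label vector")
    v10a, v01a, auc_a = _placements(a, y)
    v10b, v01b, auc_b = _placements(b, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    S = s10 / m + s01 / n
    var = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    if var <= 0:
        if np.isclose(auc_a, auc_b):
            return auc_a, auc_b, 0.0, 1.0
        return auc_a, auc_b, np.sign(auc_a - auc_b) * np.inf, 0.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2 * norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)


@dataclass
class KMCurve:
    """Right-continuous product-limit survival estimate, S(0) = 1."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __call__(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def _records_arrays(records: list[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    if not records:
        raise InvalidArgumentError("need at least one survival record")
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    return t, e


def kaplan_meier(records: list[SurvivalRecord]) -> KMCurve:
    """Product-limit estimator of local P/R-free survival."""
    t, e = _records_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    ev = kmf.event_table
    at_risk = ev["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    return KMCurve(times, surv, at_risk)


def logrank_test(
    records_group1: list[SurvivalRecord], records_group2: list[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p-value), 1 df.

    With no events in either group the curves are indistinguishable and
    (0, 1) is returned.
    """
    t1, e1 = _records_arrays(records_group1)
    t2, e2 = _records_arrays(records_group2)
    if e1.sum() + e2.sum() == 0:
        return 0.0, 1.0
    res = _ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return float(res.test_statistic), float(res.p_value)
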