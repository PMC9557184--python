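"""End-to-end orchestration: simulate -> preselect -> train -> predict -> evaluate.

A run is driven by one :class:`RunConfig` and one integer seed.  The seed
fans out deterministically to per-stage seeds through a spawned
``numpy.random.SeedSequence``, so re-running an identical config
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import MissingModalityError
from .evaluation import evaluate_model
from .fusion import FusedModel
from .momc import IMIAConfig, train_modality
from .selection import mrmr_select
from .simulate import CohortSpec, SyntheticCohort, generate_cohort
from .tables import FeatureTable

__all__ = ["RunConfig", "run_full", "ablate_sparsity", "save_model", "load_model"]

_RADIOMIC = ("CT", "PET")


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    seed: int = 0
    modalities: tuple[str, ...] = ("CT", "PET", "clinical")
    cohort: CohortSpec = field(default_factory=CohortSpec)
    feature_paths: dict | None = None  # modality -> CSV path (skips simulation)
    mrmr_k: int = 50
    imia: IMIAConfig = field(default_factory=IMIAConfig)
    fusion_scheme: str = "auc"
    threshold: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs:
            kwargs["cohort"] = CohortSpec(**kwargs["cohort"])
        if "imia" in kwargs:
            kwargs["imia"] = IMIAConfig(**kwargs["imia"])
        if "modalities" in kwargs:
            kwargs["modalities"] = tuple(kwargs["modalities"])
        return cls(**kwargs)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["modalities"] = list(self.modalities)
        d["imia"]["classifiers"] = list(self.imia.classifiers)
        if self.imia.fixed_beta is not None:
            d["imia"]["fixed_beta"] = self.imia.fixed_beta.to_dict()
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_jsonable(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _load_inputs(config: RunConfig) -> SyntheticCohort | dict:
    if config.feature_paths is not None:
        missing = [m for m in config.modalities if m not in config.feature_paths]
        if missing:
            raise MissingModalityError(f"no feature file for modalities {missing}")
        return {
            mod: FeatureTable.from_csv(config.feature_paths[mod], modality=mod)
            for mod in config.modalities
        }
    spec = replace(config.cohort, seed=_stage_seeds(config.seed)[0])
    return generate_cohort(spec)


def preselect_tables(
    tables: dict, train_idx: np.ndarray, k: int
) -> dict:
    """mRMR on training rows only; clinical tables bypass pre-selection."""
    out = {}
    for mod, table in tables.items():
        if mod in _RADIOMIC and table.n_features > k:
            names = mrmr_select(table.subset_rows(train_idx), k)
            out[mod] = table.subset_features(names)
        else:
            out[mod] = table
    return out


def save_model(model: FusedModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh)


def load_model(path: str | Path) -> FusedModel:
    with open(path) as fh:
        return FusedModel.from_dict(json.load(fh))


def run_full(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute all pipeline stages; optionally write artifacts to ``out_dir``.

    Returns the evaluation report augmented with the run manifest.  With an
    output directory the run writes ``model.json``, ``predictions.csv``,
    ``report.json`` and ``manifest.json``.
    """
    seeds = _stage_seeds(config.seed)
    data = _load_inputs(config)
    if isinstance(data, SyntheticCohort):
        cohort = data
        tables = {m: cohort.tables[m] for m in config.modalities}
        train_idx, val_idx = cohort.train_idx, cohort.val_idx
        survival_val = cohort.survival_subset(val_idx)
    else:
        tables = data
        labels = next(iter(tables.values())).labels
        from .simulate import stratified_split

        train_idx, val_idx = stratified_split(
            labels, config.cohort.validation_fraction, np.random.default_rng(seeds[1])
        )
        survival_val = None

    tables = preselect_tables(tables, train_idx, config.mrmr_k)
    train = {m: t.subset_rows(train_idx) for m, t in tables.items()}
    val = {m: t.subset_rows(val_idx) for m, t in tables.items()}

    models = [
        train_modality(train[m], config.imia, seeds[2] + j)
        for j, m in enumerate(config.modalities)
    ]
    fused_model = FusedModel.from_models(models, config.fusion_scheme)

    rows = {m: val[m].values for m in config.modalities}
    per_mod = fused_model.modality_probs(rows)
    p_fused = fused_model.predict_fused(rows)
    pred = pd.DataFrame({"patient_id": next(iter(val.values())).patient_ids})
    for k, m in enumerate(fused_model.modalities):
        pred[f"p_{m.lower()}"] = per_mod[k]
    pred["p_fused"] = p_fused
    pred["risk_class"] = (p_fused >= config.threshold).astype(int)

    report = evaluate_model(fused_model, val, survival_val, config.threshold)
    report["training"] = {m.modality: m.training_metrics for m in models}
    report["modality_weights"] = dict(
        zip(fused_model.modalities, fused_model.weights.tolist())
    )
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "package_version": __version__,
        "versions": _lib_versions(),
    }
    report["manifest"] = manifest

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_model(fused_model, out / "model.json")
        pred.to_csv(out / "predictions.csv", index=False, float_format="%.10g")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return report


def _lib_versions() -> dict:
    import sklearn

    return {"numpy": np.__version__, "pandas": pd.__version__, "sklearn": sklearn.__version__}


def ablate_sparsity(config: RunConfig, modalities: tuple[str, ...] = _RADIOMIC) -> dict:
    """Train matched with/without-sparsity arms and compare feature counts.

    Both arms share the seed and cohort; the "without" arm optimizes only
    (sensitivity, specificity).  Reports the median number of selected
    features per archived solution and the validation metrics per arm.
    """
    seeds = _stage_seeds(config.seed)
    cohort = generate_cohort(replace(config.cohort, seed=seeds[0]))
    tables = {m: cohort.tables[m] for m in modalities}
    tables = preselect_tables(tables, cohort.train_idx, config.mrmr_k)
    train = {m: t.subset_rows(cohort.train_idx) for m, t in tables.items()}
    val = {m: t.subset_rows(cohort.val_idx) for m, t in tables.items()}

    out: dict = {"arms": {}}
    for arm, with_sparsity in (("with_sparsity", True), ("without_sparsity", False)):
        imia = replace(config.imia, include_sparsity=with_sparsity)
        arm_report: dict = {}
        for j, m in enumerate(modalities):
            model = train_modality(train[m], imia, seeds[2] + j)
            probs = model.predict_table(val[m])
            from .metrics import confusion_metrics, roc_auc

            sens, spec, acc = confusion_metrics(probs, val[m].labels, config.threshold)
            arm_report[m] = {
                "median_n_selected": float(
                    np.median([s.n_selected for s in model.archive])
                ),
                "n_solutions": len(model.archive),
                "validation": {
                    "sensitivity": sens,
                    "specificity": spec,
                    "accuracy": acc,
                    "auc": roc_auc(probs, val[m].labels),
                },
            }
        out["arms"][arm] = arm_report
    return out
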