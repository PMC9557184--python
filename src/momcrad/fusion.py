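"""Multi-modality fusion of per-modality model outputs.

Per-modality models (CT radiomics, PET radiomics, clinical) each emit a
probability of local persistence/recurrence; those are combined by the
same evidential-reasoning rule used inside each modality, with modality
weights derived from training performance (proportional to training AUC
by default, balanced accuracy optionally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .er import er_fuse_rows
from .errors import InvalidArgumentError, MissingModalityError
from .momc import TrainedModalityModel

__all__ = ["modality_weights", "FusedModel", "classify"]


def modality_weights(
    models: list[TrainedModalityModel], scheme: str = "auc"
) -> np.ndarray:
    """Non-negative modality weights, sum 1, from training performance.

    ``scheme='auc'``: w_m proportional to training AUC; ``'balanced'``:
    proportional to (sens + spec)/2.  If no modality beats chance
    (all AUC <= 0.5) the weights are uniform.
    """
    if not models:
        raise InvalidArgumentError("need at least one modality model")
    if scheme == "auc":
        raw = np.array([m.training_metrics["auc"] for m in models], dtype=float)
        if np.all(raw <= 0.5):
            return np.full(len(models), 1.0 / len(models))
    elif scheme == "balanced":
        raw = np.array(
            [(m.training_metrics["sensitivity"] + m.training_metrics["specificity"]) / 2
             for m in models], dtype=float)
        if np.all(raw <= 0.5):
            return np.full(len(models), 1.0 / len(models))
    else:
        raise InvalidArgumentError(f"unknown weighting scheme {scheme!r}")
    return raw / raw.sum()


def classify(probability: float, threshold: float = 0.5) -> int:
    """1 = high-risk (predicted P/R) when p >= threshold (inclusive), else 0."""
    return int(probability >= threshold)


@dataclass
class FusedModel:
    """ER-fused set of per-modality models with modality weights."""

    models: dict[str, TrainedModalityModel]  # modality -> model
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.models) or np.any(self.weights < 0):
            raise InvalidArgumentError("one non-negative weight per modality required")

    @property
    def modalities(self) -> list[str]:
        return list(self.models.keys())

    @classmethod
    def from_models(
        cls, models: list[TrainedModalityModel], scheme: str = "auc"
    ) -> "FusedModel":
        return cls({m.modality: m for m in models}, modality_weights(models, scheme))

    def modality_probs(self, rows: dict[str, np.ndarray]) -> np.ndarray:
        """Per-modality probabilities, shape (n_modalities, n_samples)."""
        out = []
        for mod, model in self.models.items():
            if mod not in rows:
                raise MissingModalityError(
                    f"no feature rows supplied for modality {mod!r}"
                )
            out.append(model.predict_proba(rows[mod]))
        return np.stack(out)

    def predict_fused(self, rows: dict[str, np.ndarray]) -> np.ndarray:
        """ER-fused probability per sample; requires every modality's rows."""
        return er_fuse_rows(self.weights, self.modality_probs(rows))

    def predict_risk(self, rows: dict[str, np.ndarray], threshold: float = 0.5) -> np.ndarray:
        return (self.predict_fused(rows) >= threshold).astype(int)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "models": {mod: m.to_dict() for mod, m in self.models.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FusedModel":
        return cls(
            {mod: TrainedModalityModel.from_dict(md) for mod, md in d["models"].items()},
            np.array(d["weights"]),
        )
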