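"""Patients x features tables with binary outcome labels."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = ["FeatureTable"]


@dataclass
class FeatureTable:
    """A patients x named-features matrix plus binary outcome labels.

    Label 1 means local persistence/recurrence.  No missing values are
    allowed: clinical categories must already be encoded numerically.
    """

    patient_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray
    modality: str = "CT"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, p = self.values.shape
        if len(self.patient_ids) != n or len(self.labels) != n:
            raise InvalidArgumentError("row count mismatch between ids/labels/values")
        if len(self.feature_names) != p:
            raise InvalidArgumentError("feature name count mismatch")
        if len(set(self.feature_names)) != p:
            raise InvalidArgumentError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("feature values must be finite (encode first)")
        if not np.isin(self.labels, [0, 1]).all():
            raise InvalidArgumentError("labels must be binary 0/1")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, idx: np.ndarray) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            [self.patient_ids[i] for i in idx],
            list(self.feature_names),
            self.values[idx],
            self.labels[idx],
            self.modality,
        )

    def subset_features(self, names: list[str]) -> "FeatureTable":
        pos = [self.feature_names.index(n) for n in names]
        return FeatureTable(
            list(self.patient_ids), list(names), self.values[:, pos], self.labels, self.modality
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "patient_id", self.patient_ids)
        df["label"] = self.labels
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, modality: str = "CT") -> "FeatureTable":
        cols = [c for c in df.columns if c not in ("patient_id", "label")]
        return cls(
            df["patient_id"].astype(str).tolist(),
            cols,
            df[cols].to_numpy(dtype=float),
            df["label"].to_numpy(dtype=int),
            modality,
        )

    @classmethod
    def from_csv(cls, path: str | Path, modality: str = "CT") -> "FeatureTable":
        return cls.from_frame(pd.read_csv(path), modality)
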