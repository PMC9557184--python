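"""mRMR feature pre-selection.

Minimum-redundancy-maximum-relevance (Peng's MID criterion): greedily pick
the feature maximizing MI(feature; label) minus the mean MI with the
already-selected set.  Features are discretized to three levels around
mu +/- sigma first — the classic mRMR convention for continuous inputs.
The radiomic tables are pre-selected to 50 features per imaging modality;
clinical covariates bypass mRMR.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError
from .tables import FeatureTable

__all__ = ["discretize", "mutual_information", "mrmr_select"]


def discretize(values: np.ndarray) -> np.ndarray:
    """3-level coding: below mu-sigma -> 0, within [mu-sigma, mu+sigma] -> 1, above -> 2.

    A zero-variance column codes to all 1.  The coding is invariant to
    affine transforms of the column.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise InvalidArgumentError("discretize requires finite values")
    mu, sigma = v.mean(), v.std()
    if sigma == 0:
        return np.ones(len(v), dtype=np.int64)
    out = np.ones(len(v), dtype=np.int64)
    out[v < mu - sigma] = 0
    out[v > mu + sigma] = 2
    return out


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """MI in bits between two integer-coded columns, with 0*log(0) = 0."""
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y) or len(x) == 0:
        raise InvalidArgumentError("columns must have equal, non-zero length")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny) / len(x)
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log2(joint[nz] / (px @ py)[nz])).sum())


def mrmr_select(table: FeatureTable, k: int = 50) -> list[str]:
    """Greedy MID mRMR: exactly ``k`` feature names in selection order.

    Step 1 picks the feature with maximal MI with the label; each further
    step maximizes MI(f; label) - mean_{s in S} MI(f; s).  Ties break by
    column order.
    """
    if k > table.n_features:
        raise InvalidArgumentError(
            f"cannot select {k} from {table.n_features} features"
        )
    disc = np.stack([discretize(table.values[:, j]) for j in range(table.n_features)], axis=1)
    y = table.labels
    relevance = np.array([mutual_information(disc[:, j], y) for j in range(table.n_features)])

    selected: list[int] = []
    redundancy_sum = np.zeros(table.n_features)
    remaining = list(range(table.n_features))
    for _ in range(k):
        if not selected:
            scores = relevance
        else:
            scores = relevance - redundancy_sum / len(selected)
        best = max(remaining, key=lambda j: (scores[j], -j))
        selected.append(best)
        remaining.remove(best)
        for j in remaining:
            redundancy_sum[j] += mutual_information(disc[:, j], disc[:, best])
    return [table.feature_names[j] for j in selected]
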