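"""Evidential-reasoning (ER) combination of weighted probability sources.

Each source i with weight w_i and probability p_i contributes belief
masses over the two-hypothesis frame {positive, negative}:

    m_i(+) = w_i * p_i        m_i(-) = w_i * (1 - p_i)
    m_i(theta) = 1 - w_i      (unassigned / residual mass)

Sources are combined pairwise by the conjunctive rule with conflict
normalization:

    m(+)  <-  [m1(+)m2(+) + m1(+)m2(th) + m1(th)m2(+)] / K
    m(-)  <-  [m1(-)m2(-) + m1(-)m2(th) + m1(th)m2(-)] / K
    m(th) <-  m1(th)m2(th) / K
    K = 1 - m1(+)m2(-) - m1(-)m2(+)

The fused probability assigns the residual mass proportionally to the
combined singleton beliefs: p = m(+) + m(theta) * m(+)/(m(+)+m(-)).
With no singleton belief at all (all weights zero, or total conflict)
the fused probability is the non-informative 0.5.
"""

from __future__ import annotations

import numpy as np

__all__ = ["er_fuse", "er_fuse_rows"]

_EPS = 1e-15


def er_fuse_rows(weights: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Fuse m sources for many samples at once.

    Parameters
    ----------
    weights : (m,) non-negative source weights, at most 1 each (normally
        normalized to sum 1 across sources).
    probs : (m, n) per-source probability of the positive hypothesis.

    Returns
    -------
    (n,) fused probabilities in [0, 1].
    """
    weights = np.asarray(weights, dtype=float)
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    m, n = probs.shape
    if weights.shape != (m,):
        raise ValueError("one weight per source required")
    if np.any(weights < -1e-12) or np.any(weights > 1 + 1e-12):
        raise ValueError("source weights must lie in [0, 1]")
    weights = np.clip(weights, 0.0, 1.0)

    mp = np.full(n, weights[0] * 1.0) * probs[0]
    mn = weights[0] * (1.0 - probs[0])
    mt = np.full(n, 1.0 - weights[0])
    for i in range(1, m):
        qp = weights[i] * probs[i]
        qn = weights[i] * (1.0 - probs[i])
        qt = 1.0 - weights[i]
        K = 1.0 - mp * qn - mn * qp
        conflict = K <= _EPS
        K = np.where(conflict, 1.0, K)
        new_p = (mp * qp + mp * qt + mt * qp) / K
        new_n = (mn * qn + mn * qt + mt * qn) / K
        new_t = (mt * qt) / K
        # total conflict (w_i = w_j = 1, p=1 vs p=0): no evidence survives
        mp = np.where(conflict, 0.0, new_p)
        mn = np.where(conflict, 0.0, new_n)
        mt = np.where(conflict, 1.0, new_t)

    denom = mp + mn
    pbar = np.where(denom > _EPS, mp / np.where(denom > _EPS, denom, 1.0), 0.5)
    return np.clip(mp + mt * pbar, 0.0, 1.0)


def er_fuse(weights, probs) -> float:
    """Scalar convenience wrapper around :func:`er_fuse_rows`."""
    probs = np.asarray(probs, dtype=float).reshape(-1, 1)
    return float(er_fuse_rows(np.asarray(weights, dtype=float), probs)[0])
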