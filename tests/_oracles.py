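"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (explicit
loops, textbook formulas) and stays independent of the package internals
it checks.
"""

import numpy as np

DIRECTIONS = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def quantize_oracle(values, mask, n_levels):
    """Equal-width binning of in-mask values to 1..n_levels (constant -> 1)."""
    v = values[mask]
    lo, hi = v.min(), v.max()
    q = np.zeros(values.shape, dtype=int)
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        if hi == lo:
            q[idx] = 1
        else:
            level = int((values[idx] - lo) / (hi - lo) * n_levels)
            q[idx] = min(level, n_levels - 1) + 1
    return q


def glcm_oracle(values, mask, n_levels, distance):
    """Direction-merged symmetric normalized GLCM by explicit pair counting.

    Returns None when no valid voxel pair exists at the distance.
    """
    q = quantize_oracle(values, mask, n_levels)
    shape = values.shape
    counts = np.zeros((n_levels, n_levels), dtype=float)
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                for dz, dy, dx in DIRECTIONS:
                    z2, y2, x2 = z + distance * dz, y + distance * dy, x + distance * dx
                    if not (0 <= z2 < shape[0] and 0 <= y2 < shape[1] and 0 <= x2 < shape[2]):
                        continue
                    if not mask[z2, y2, x2]:
                        continue
                    i, j = q[z, y, x] - 1, q[z2, y2, x2] - 1
                    counts[i, j] += 1
                    counts[j, i] += 1  # symmetrization
    total = counts.sum()
    if total == 0:
        return None
    return counts / total


def glcm_stats_oracle(P):
    """Textbook Haralick statistics of a normalized symmetric GLCM."""
    L = P.shape[0]
    stats = {}
    mu = 0.0
    for i in range(L):
        for j in range(L):
            mu += (i + 1) * P[i, j]
    var = 0.0
    for i in range(L):
        for j in range(L):
            var += (i + 1 - mu) ** 2 * P[i, j]
    energy = contrast = homog = ent = sumavg = dissim = autoc = clus = 0.0
    for i in range(L):
        for j in range(L):
            p = P[i, j]
            energy += p * p
            contrast += (i - j) ** 2 * p
            homog += p / (1 + (i - j) ** 2)
            if p > 0:
                ent -= p * np.log2(p)
            sumavg += (i + j + 2) * p
            dissim += abs(i - j) * p
            autoc += (i + 1) * (j + 1) * p
            clus += (i + 1 + j + 1 - 2 * mu) ** 2 * p
    corr = (autoc - mu * mu) / var if var > 0 else 0.0
    return {
        "energy": energy, "contrast": contrast, "correlation": corr,
        "homogeneity": homog, "entropy": ent, "variance": var,
        "sum_average": sumavg, "dissimilarity": dissim,
        "autocorrelation": autoc, "cluster_tendency": clus,
    }


def auc_pair_oracle(scores, labels):
    """O(n^2) pairwise-comparison AUC with ties counted 0.5."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def er_recursion_oracle(weights, probs):
    """Step-by-step two-hypothesis ER combination, coded independently."""
    m_pos, m_neg, m_theta = weights[0] * probs[0], weights[0] * (1 - probs[0]), 1 - weights[0]
    for w, p in zip(weights[1:], probs[1:]):
        n_pos, n_neg, n_theta = w * p, w * (1 - p), 1 - w
        k = 1.0 - m_pos * n_neg - m_neg * n_pos
        m_pos, m_neg, m_theta = (
            (m_pos * n_pos + m_pos * n_theta + m_theta * n_pos) / k,
            (m_neg * n_neg + m_neg * n_theta + m_theta * n_neg) / k,
            (m_theta * n_theta) / k,
        )
    if m_pos + m_neg == 0:
        return 0.5
    return m_pos + m_theta * m_pos / (m_pos + m_neg)


def km_hand(times, events):
    """Product-limit estimate at each distinct event time, by hand."""
    order = np.argsort(times)
    times = np.asarray(times, dtype=float)[order]
    events = np.asarray(events, dtype=int)[order]
    s = 1.0
    out = {}
    n_at_risk = len(times)
    i = 0
    while i < len(times):
        t = times[i]
        d = sum(events[j] for j in range(len(times)) if times[j] == t)
        n = sum(1 for j in range(len(times)) if times[j] >= t)
        if d > 0:
            s *= 1 - d / n
        out[t] = s
        i += sum(1 for j in range(len(times)) if times[j] == t)
    return out


def logrank_hand(t1, e1, t2, e2):
    """Observed-minus-expected log-rank chi-square via explicit worksheets."""
    all_times = sorted({t for t, e in zip(list(t1) + list(t2), list(e1) + list(e2)) if e == 1})
    O1 = E1 = V = 0.0
    for t in all_times:
        n1 = sum(1 for x in t1 if x >= t)
        n2 = sum(1 for x in t2 if x >= t)
        d1 = sum(1 for x, e in zip(t1, e1) if x == t and e == 1)
        d2 = sum(1 for x, e in zip(t2, e2) if x == t and e == 1)
        n, d = n1 + n2, d1 + d2
        if n == 0 or d == 0:
            continue
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0
    return (O1 - E1) ** 2 / V
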