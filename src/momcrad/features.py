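"""Radiomic feature extraction: geometry, intensity and 3-D GLCM texture.

The per-modality signature is 257 features: 8 geometry features computed
from the binary region, 9 first-order intensity statistics of the in-region
voxel values, and 240 gray-level co-occurrence matrix (GLCM) features —
10 Haralick-family statistics for each combination of 4 quantization
settings (8, 16, 32, 64 gray levels) and 6 voxel distances (1..6).

GLCMs are 3-D: voxel pairs are accumulated over the 13 unique direction
vectors at the given (Chebyshev) distance, with both voxels inside the
region, then symmetrized and normalized to a probability matrix
(merged-direction aggregation).  A ``per_direction`` flag switches to
averaging the 10 statistics over per-direction matrices instead.

Degenerate situations never produce NaN: a constant region maps every
voxel to gray level 1 (so energy 1, contrast 0); correlation of a
zero-variance GLCM is defined as 0; a (levels, distance) setting with no
valid voxel pairs falls back to the single-bin constant-region convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import kurtosis, skew
from skimage import measure

from .errors import DegenerateGLCMError, EmptyRegionError
from .imaging import RegionMask, VolumetricImage

__all__ = [
    "FeatureVector",
    "GLCMSpec",
    "GRAY_LEVELS",
    "DISTANCES",
    "GLCM_STATISTICS",
    "DIRECTIONS_3D",
    "geometry_features",
    "intensity_features",
    "quantize",
    "glcm_matrix",
    "glcm_statistics",
    "glcm_features",
    "extract_all",
]

GRAY_LEVELS = (8, 16, 32, 64)
DISTANCES = (1, 2, 3, 4, 5, 6)
GLCM_STATISTICS = (
    "energy",
    "contrast",
    "correlation",
    "homogeneity",
    "entropy",
    "variance",
    "sum_average",
    "dissimilarity",
    "autocorrelation",
    "cluster_tendency",
)

# the 13 unique 3-D direction vectors (the other 13 are their negatives,
# covered by symmetrization)
DIRECTIONS_3D = (
    (0, 0, 1),
    (0, 1, 0),
    (1, 0, 0),
    (0, 1, 1),
    (0, 1, -1),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)


@dataclass
class FeatureVector:
    """Ordered, uniquely named scalar features for one region/modality."""

    names: list[str]
    values: np.ndarray
    modality: str = "CT"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names and values must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.names)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


@dataclass
class GLCMSpec:
    n_gray_levels: int = 32
    distance_vox: int = 1
    per_direction: bool = False

    def __post_init__(self) -> None:
        if self.n_gray_levels < 2:
            raise ValueError("need at least 2 gray levels")
        if self.distance_vox < 1:
            raise ValueError("distance must be >= 1 voxel")


def _require_foreground(mask: RegionMask) -> None:
    if mask.n_foreground == 0:
        raise EmptyRegionError("region mask has no foreground voxels")


# ---------------------------------------------------------------------------
# Geometry


def _max_diameter(coords_mm: np.ndarray) -> float:
    """Largest pairwise Euclidean distance between foreground voxel centres."""
    pts = coords_mm
    if len(pts) > 500:
        try:
            hull = ConvexHull(pts, qhull_options="QJ")
            pts = pts[hull.vertices]
        except QhullError:
            pass  # degenerate (coplanar) regions: fall through to all pairs
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def geometry_features(mask: RegionMask) -> FeatureVector:
    """Eight shape descriptors of the region (units: mm, mm**2, mm**3).

    Surface area comes from a marching-cubes mesh of the (zero-padded)
    mask; axis lengths from the eigenvalues of the voxel-coordinate
    covariance, using the 4*sqrt(lambda) ellipsoid convention.
    """
    _require_foreground(mask)
    sp = np.asarray(mask.spacing)
    voxel_vol = float(np.prod(sp))
    n = mask.n_foreground
    volume = n * voxel_vol

    # light Gaussian anti-aliasing before marching cubes: the staircase
    # surface of a raw binary grid overestimates area by ~8%; tiny regions
    # that would vanish under smoothing fall back to the raw mask
    padded = np.pad(mask.values.astype(float), 1)
    smoothed = ndimage.gaussian_filter(padded, sigma=0.7)
    if smoothed.max() <= 0.5:
        smoothed = padded
    verts, faces, _, _ = measure.marching_cubes(smoothed, level=0.5, spacing=tuple(sp))
    area = float(measure.mesh_surface_area(verts, faces))

    coords = np.argwhere(mask.values) * sp
    diameter = _max_diameter(coords)

    cov = np.cov(coords, rowvar=False) if len(coords) > 1 else np.zeros((3, 3))
    eigvals = np.clip(np.linalg.eigvalsh(np.atleast_2d(cov)), 0.0, None)
    major = 4.0 * float(np.sqrt(eigvals[-1]))
    minor = 4.0 * float(np.sqrt(eigvals[0]))
    elongation = minor / major if major > 0 else 1.0

    sphericity = np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / area
    compactness = volume / (np.sqrt(np.pi) * area**1.5)

    names = [
        "geom_volume_mm3",
        "geom_surface_area_mm2",
        "geom_surface_to_volume",
        "geom_sphericity",
        "geom_compactness",
        "geom_max_diameter_mm",
        "geom_major_axis_mm",
        "geom_elongation",
    ]
    values = [volume, area, area / volume, sphericity, compactness, diameter, major, elongation]
    return FeatureVector(names, np.array(values))


# ---------------------------------------------------------------------------
# Intensity


def intensity_features(image: VolumetricImage, mask: RegionMask) -> FeatureVector:
    """Nine first-order statistics of the in-region voxel values.

    Standard deviation is the population SD; kurtosis is Fisher (normal = 0);
    entropy uses a 64-bin histogram over the in-region range, base 2.
    Constant regions get SD, skewness, kurtosis and entropy all 0.
    """
    _require_foreground(mask)
    mask.require_alignment(image)
    v = image.values[mask.values]
    constant = v.max() == v.min()
    if constant:
        skw = kurt = entropy = std = 0.0
    else:
        std = float(v.std())
        skw = float(skew(v))
        kurt = float(kurtosis(v, fisher=True))
        hist, _ = np.histogram(v, bins=64, range=(v.min(), v.max()))
        p = hist[hist > 0] / hist.sum()
        entropy = float(-(p * np.log2(p)).sum())
    names = [
        "int_min",
        "int_max",
        "int_mean",
        "int_median",
        "int_std",
        "int_skewness",
        "int_kurtosis",
        "int_energy",
        "int_entropy",
    ]
    values = [
        float(v.min()),
        float(v.max()),
        float(v.mean()),
        float(np.median(v)),
        std,
        skw,
        kurt,
        float((v**2).sum()),
        entropy,
    ]
    return FeatureVector(names, np.array(values))


# ---------------------------------------------------------------------------
# GLCM


def quantize(image: VolumetricImage, mask: RegionMask, n_levels: int) -> np.ndarray:
    """Equal-width quantization of in-region values to levels 1..n_levels.

    A constant region maps every voxel to level 1.  Voxels outside the mask
    are level 0 and never enter pair counting.
    """
    _require_foreground(mask)
    q = np.zeros(image.shape, dtype=np.int32)
    v = image.values[mask.values]
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        q[mask.values] = 1
    else:
        lv = np.floor((image.values[mask.values] - lo) / (hi - lo) * n_levels).astype(np.int32)
        q[mask.values] = np.clip(lv, 0, n_levels - 1) + 1
    return q


def _pair_counts(q: np.ndarray, fg: np.ndarray, offset: tuple[int, int, int], n_levels: int) -> np.ndarray:
    """Directed co-occurrence counts for one displacement vector."""
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, o in enumerate(offset):
        if o >= 0:
            src[ax] = slice(0, q.shape[ax] - o) if o else slice(None)
            dst[ax] = slice(o, None) if o else slice(None)
        else:
            src[ax] = slice(-o, None)
            dst[ax] = slice(0, q.shape[ax] + o)
    a, b = q[tuple(src)], q[tuple(dst)]
    valid = fg[tuple(src)] & fg[tuple(dst)]
    if valid.any():
        i, j = a[valid] - 1, b[valid] - 1
        np.add.at(counts, (i, j), 1)
    return counts


def glcm_matrix(
    image: VolumetricImage, mask: RegionMask, spec: GLCMSpec
) -> np.ndarray:
    """Direction-merged symmetric normalized GLCM (n_levels x n_levels).

    Pair counts are accumulated over the 13 unique 3-D directions scaled by
    ``distance_vox``, symmetrized (each pair counted in both orders) and
    normalized to sum 1.  Raises :class:`DegenerateGLCMError` when no valid
    in-mask voxel pair exists at the requested distance.
    """
    mask.require_alignment(image)
    q = quantize(image, mask, spec.n_gray_levels)
    fg = mask.values
    L, d = spec.n_gray_levels, spec.distance_vox
    total = np.zeros((L, L), dtype=np.int64)
    for direction in DIRECTIONS_3D:
        off = tuple(d * c for c in direction)
        if any(abs(o) >= s for o, s in zip(off, q.shape)):
            continue
        total += _pair_counts(q, fg, off, L)
    total = total + total.T
    s = total.sum()
    if s == 0:
        raise DegenerateGLCMError(
            f"no voxel pairs at distance {d} for {L}-level GLCM"
        )
    return total / s


def glcm_statistics(P: np.ndarray) -> dict[str, float]:
    """Ten Haralick-family statistics of a normalized symmetric GLCM.

    Gray levels are indexed 1..L.  Correlation of a zero-variance matrix is
    defined as 0.
    """
    L = P.shape[0]
    i = np.arange(1, L + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float((i * px).sum())
    var = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(var)
    autocorr = float((ii * jj * P).sum())
    nz = P > 0
    return {
        "energy": float((P**2).sum()),
        "contrast": float(((ii - jj) ** 2 * P).sum()),
        "correlation": float((autocorr - mu * mu) / var) if var > 0 else 0.0,
        "homogeneity": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "entropy": float(-(P[nz] * np.log2(P[nz])).sum()),
        "variance": var,
        "sum_average": float(((ii + jj) * P).sum()),
        "dissimilarity": float((np.abs(ii - jj) * P).sum()),
        "autocorrelation": autocorr,
        "cluster_tendency": float(((ii + jj - 2.0 * mu) ** 2 * P).sum()),
    }


# constant-region / no-pairs convention: statistics of the single-bin GLCM
_DEGENERATE_STATS = {
    "energy": 1.0,
    "contrast": 0.0,
    "correlation": 0.0,
    "homogeneity": 1.0,
    "entropy": 0.0,
    "variance": 0.0,
    "sum_average": 2.0,
    "dissimilarity": 0.0,
    "autocorrelation": 1.0,
    "cluster_tendency": 0.0,
}


def glcm_features(
    image: VolumetricImage,
    mask: RegionMask,
    per_direction: bool = False,
) -> FeatureVector:
    """All 240 GLCM texture features: 10 statistics x 4 level settings x 6 distances."""
    _require_foreground(mask)
    names: list[str] = []
    values: list[float] = []
    for L in GRAY_LEVELS:
        for d in DISTANCES:
            stats = _glcm_stats_at(image, mask, L, d, per_direction)
            for stat in GLCM_STATISTICS:
                names.append(f"glcm_{stat}_g{L}_d{d}")
                values.append(stats[stat])
    return FeatureVector(names, np.array(values))


def _glcm_stats_at(
    image: VolumetricImage, mask: RegionMask, L: int, d: int, per_direction: bool
) -> dict[str, float]:
    if not per_direction:
        try:
            P = glcm_matrix(image, mask, GLCMSpec(L, d))
        except DegenerateGLCMError:
            return dict(_DEGENERATE_STATS)
        return glcm_statistics(P)
    # per-direction averaging: statistics of each direction's symmetric GLCM,
    # averaged over the directions that have pairs
    q = quantize(image, mask, L)
    fg = mask.values
    acc: dict[str, float] = {k: 0.0 for k in GLCM_STATISTICS}
    n_ok = 0
    for direction in DIRECTIONS_3D:
        off = tuple(d * c for c in direction)
        if any(abs(o) >= s for o, s in zip(off, q.shape)):
            continue
        C = _pair_counts(q, fg, off, L)
        C = C + C.T
        if C.sum() == 0:
            continue
        st = glcm_statistics(C / C.sum())
        for k in GLCM_STATISTICS:
            acc[k] += st[k]
        n_ok += 1
    if n_ok == 0:
        return dict(_DEGENERATE_STATS)
    return {k: v / n_ok for k, v in acc.items()}


# ---------------------------------------------------------------------------


def extract_all(image: VolumetricImage, mask: RegionMask) -> FeatureVector:
    """The full 257-feature signature: geometry, intensity, GLCM, in that order.

    Inputs are expected preprocessed (isotropic grid; CT soft-tissue
    windowed mask; PET in SUV).  Order is deterministic.
    """
    geo = geometry_features(mask)
    inten = intensity_features(image, mask)
    tex = glcm_features(image, mask)
    return FeatureVector(
        geo.names + inten.names + tex.names,
        np.concatenate([geo.values, inten.values, tex.values]),
        modality=image.modality,
    )
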