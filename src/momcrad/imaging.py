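"""Volumetric image containers, NIfTI I/O and preprocessing.

Images are 3-D scalar grids with anisotropic voxel spacing in mm.  CT is
carried in raw Hounsfield units; PET either as activity concentration
(Bq/mL) or as standardized uptake value (SUV).  Preprocessing follows the
usual post-treatment radiomics recipe: resample everything to an isotropic
1 mm grid, restrict the tumour mask to soft tissue on CT (HU in
[-150, 180]), and convert PET activity to body-weight SUV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import EmptyRegionError, InvalidArgumentError

__all__ = [
    "VolumetricImage",
    "RegionMask",
    "AcquisitionInfo",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "resample_isotropic",
    "soft_tissue_mask",
    "compute_suv",
    "suv_threshold_region",
]

_VALID_UNITS = {"CT": {"HU"}, "PET": {"Bq/mL", "SUV"}}


@dataclass
class VolumetricImage:
    """A 3-D scalar grid with voxel spacing (dx, dy, dz) in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    modality: str  # "CT" or "PET"
    units: str  # "HU", "Bq/mL" or "SUV"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise InvalidArgumentError("image grid must be 3-D with dims >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or not all(
            np.isfinite(s) and s > 0 for s in self.spacing
        ):
            raise InvalidArgumentError("spacing must be three positive finite mm values")
        if self.modality not in _VALID_UNITS:
            raise InvalidArgumentError(f"unknown modality {self.modality!r}")
        if self.units not in _VALID_UNITS[self.modality]:
            raise InvalidArgumentError(
                f"units {self.units!r} invalid for modality {self.modality!r}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class RegionMask:
    """A binary 3-D grid aligned to an image; the analysis (GTV) region."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise InvalidArgumentError("mask grid must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if not all(np.isfinite(s) and s > 0 for s in self.spacing):
            raise InvalidArgumentError("spacing must be positive and finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_foreground(self) -> int:
        return int(self.values.sum())

    def require_alignment(self, image: VolumetricImage) -> None:
        if self.shape != image.shape or not np.allclose(self.spacing, image.spacing):
            raise InvalidArgumentError("mask is not aligned to the image grid")


@dataclass
class AcquisitionInfo:
    """PET acquisition metadata needed for body-weight SUV."""

    injected_dose_bq: float
    body_weight_g: float
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        if not (np.isfinite(self.injected_dose_bq) and self.injected_dose_bq > 0):
            raise InvalidArgumentError("injected dose must be > 0 Bq")
        if not (np.isfinite(self.body_weight_g) and self.body_weight_g > 0):
            raise InvalidArgumentError("body weight must be > 0 g")

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionInfo":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            injected_dose_bq=d["injected_dose_bq"],
            body_weight_g=d["body_weight_g"],
            decay_corrected=d.get("decay_corrected", True),
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "injected_dose_bq": self.injected_dose_bq,
                    "body_weight_g": self.body_weight_g,
                    "decay_corrected": self.decay_corrected,
                },
                fh,
                indent=2,
            )


# ---------------------------------------------------------------------------
# NIfTI I/O.  Spacing is carried on a diagonal RAS affine; indices 0-based.


def save_image(image: VolumetricImage, path: str | Path) -> None:
    affine = np.diag(list(image.spacing) + [1.0])
    nib.save(nib.Nifti1Image(image.values.astype(np.float32), affine), str(path))


def load_image(path: str | Path, modality: str, units: str) -> VolumetricImage:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumetricImage(np.asanyarray(img.dataobj, dtype=float), spacing, modality, units)


def save_mask(mask: RegionMask, path: str | Path) -> None:
    affine = np.diag(list(mask.spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.values.astype(np.uint8), affine), str(path))


def load_mask(path: str | Path) -> RegionMask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return RegionMask(np.asanyarray(img.dataobj) > 0.5, spacing)


# ---------------------------------------------------------------------------
# Preprocessing


def _resample_grid(
    values: np.ndarray,
    spacing: tuple[float, float, float],
    target: float,
    order: int,
) -> np.ndarray:
    new_shape = tuple(
        max(1, int(round(n * s / target))) for n, s in zip(values.shape, spacing)
    )
    # voxel centre of output index i sits at physical position i * target mm;
    # source index = position / source spacing.  Edge samples clamp to the
    # nearest source voxel (constant extrapolation).
    coords = np.meshgrid(
        *[np.arange(n) * target / s for n, s in zip(new_shape, spacing)],
        indexing="ij",
    )
    return ndimage.map_coordinates(
        values.astype(float), np.stack(coords), order=order, mode="nearest"
    )


def resample_isotropic(
    image: VolumetricImage | RegionMask,
    target_spacing_mm: float = 1.0,
    is_mask: bool | None = None,
) -> VolumetricImage | RegionMask:
    """Resample to an isotropic grid (default 1 mm).

    Intensity images are interpolated tri-linearly; masks nearest-neighbour
    so the output stays binary.  Output dimension along each axis is
    ``round(dim * spacing / target)`` with a minimum of 1.
    """
    if not (np.isfinite(target_spacing_mm) and target_spacing_mm > 0):
        raise InvalidArgumentError("target spacing must be a positive scalar")
    if is_mask is None:
        is_mask = isinstance(image, RegionMask)
    t = float(target_spacing_mm)
    if is_mask:
        vals = _resample_grid(image.values.astype(float), image.spacing, t, order=0)
        return RegionMask(vals > 0.5, (t, t, t))
    vals = _resample_grid(image.values, image.spacing, t, order=1)
    return VolumetricImage(vals, (t, t, t), image.modality, image.units)


def soft_tissue_mask(
    ct: VolumetricImage,
    mask: RegionMask,
    hu_low: float = -150.0,
    hu_high: float = 180.0,
) -> RegionMask:
    """Restrict a mask to soft tissue: keep voxels with HU in [hu_low, hu_high].

    Bounds are inclusive.  Raises :class:`EmptyRegionError` if nothing remains.
    """
    if ct.modality != "CT" or ct.units != "HU":
        raise InvalidArgumentError("soft-tissue windowing requires a CT image in HU")
    mask.require_alignment(ct)
    keep = mask.values & (ct.values >= hu_low) & (ct.values <= hu_high)
    if not keep.any():
        raise EmptyRegionError("HU window removed every voxel of the region")
    return RegionMask(keep, mask.spacing)


def compute_suv(pet: VolumetricImage, acq: AcquisitionInfo) -> VolumetricImage:
    """Body-weight SUV: activity [Bq/mL] x body weight [g] / injected dose [Bq].

    Activity is assumed decay-corrected to injection time.
    """
    if pet.modality != "PET" or pet.units != "Bq/mL":
        raise InvalidArgumentError("SUV conversion requires PET activity in Bq/mL")
    suv = pet.values * (acq.body_weight_g / acq.injected_dose_bq)
    return VolumetricImage(suv, pet.spacing, "PET", "SUV")


def suv_threshold_region(
    suv: VolumetricImage,
    threshold: float = 2.5,
    seed_mask: RegionMask | None = None,
) -> RegionMask:
    """Voxels with SUV >= threshold (inclusive), as a region mask.

    With a seed mask, only 26-connected components intersecting the seed are
    kept.  Raises :class:`EmptyRegionError` on an empty result.
    """
    if suv.units != "SUV":
        raise InvalidArgumentError("thresholding requires an image in SUV units")
    fg = suv.values >= threshold
    if seed_mask is not None:
        seed_mask.require_alignment(suv)
        labels, n = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=int))
        keep_ids = np.unique(labels[seed_mask.values & (labels > 0)])
        fg = np.isin(labels, keep_ids) & (labels > 0)
    if not fg.any():
        raise EmptyRegionError(f"no voxels with SUV >= {threshold}")
    return RegionMask(fg, suv.spacing)
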