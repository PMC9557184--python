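"""Synthetic phantoms and cohorts for end-to-end exercising of the pipeline.

No post-treatment PET/CT dataset of this kind is publicly deposited, so
every input is simulated.  The phantom generator builds a sphere-with-lobes
lesion in a CT/PET volume pair for the feature extractor; the cohort
generator emulates the study population — 328 patients at 21% positive
prevalence with a 4:1 label-stratified train/validation split — with
per-modality feature tables carrying a small planted informative subset,
Table-1-style clinical covariates, and exponential follow-up times.

Radiomic redundancy is mimicked by block-correlated Gaussian noise
features (rho = 0.6 within blocks of 10).  Informative features are
independent standard normals shifted by a standardized effect size d in
positives, so the per-modality Bayes-optimal AUC has the closed form
Phi(sqrt(sum d_i^2) / sqrt(2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import norm

from .errors import InvalidArgumentError
from .imaging import RegionMask, VolumetricImage
from .metrics import SurvivalRecord
from .tables import FeatureTable

__all__ = [
    "generate_phantom",
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "effect_sizes_for_auc",
    "stratified_split",
    "encode_clinical",
]


# ---------------------------------------------------------------------------
# Phantom


def generate_phantom(
    size_mm: int = 48,
    lesion_radius_mm: float = 10.0,
    lesion_suv: float = 6.0,
    background_suv: float = 1.0,
    hu_range: tuple[float, float] = (0.0, 80.0),
    background_hu: float = -120.0,
    noise_sd: float = 0.1,
    ct_noise_sd: float = 8.0,
    seed: int = 0,
) -> tuple[VolumetricImage, VolumetricImage, RegionMask]:
    """A sphere-with-lobes lesion in aligned CT/PET cubes at 1 mm spacing.

    The PET lesion sits at ``lesion_suv`` (default 6, comfortably above the
    2.5 SUV rule); the CT lesion carries a linear soft-tissue gradient over
    ``hu_range``.  ``noise_sd`` is Gaussian noise on the PET (SUV units),
    ``ct_noise_sd`` on the CT (HU).  With both zero the volumes are
    piecewise constant/linear.  The mask is the true lesion extent.
    """
    n = int(size_mm)
    r = float(lesion_radius_mm)
    lobe_r = 0.45 * r
    lobe_off = 0.9 * r
    if r + lobe_off + lobe_r >= n / 2:
        raise InvalidArgumentError("lesion (with lobes) does not fit in the volume")
    rng = np.random.default_rng(seed)
    c = (n - 1) / 2.0
    zz, yy, xx = np.meshgrid(*([np.arange(n) - c] * 3), indexing="ij")

    def ball(cz, cy, cx, radius):
        return (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2

    mask = ball(0, 0, 0, r)
    mask |= ball(lobe_off, 0.3 * r, 0, lobe_r)
    mask |= ball(-0.3 * r, -lobe_off, 0.2 * r, lobe_r)

    pet_vals = np.full((n, n, n), float(background_suv))
    pet_vals[mask] = lesion_suv
    if noise_sd > 0:
        pet_vals = pet_vals + rng.normal(0, noise_sd, pet_vals.shape)
        pet_vals = np.clip(pet_vals, 0, None)

    hu_lo, hu_hi = hu_range
    gradient = (xx - xx.min()) / (xx.max() - xx.min())  # linear soft-tissue texture
    ct_vals = np.full((n, n, n), float(background_hu))
    ct_vals[mask] = hu_lo + (hu_hi - hu_lo) * gradient[mask]
    if ct_noise_sd > 0:
        ct_vals = ct_vals + rng.normal(0, ct_noise_sd, ct_vals.shape)

    spacing = (1.0, 1.0, 1.0)
    ct = VolumetricImage(ct_vals, spacing, "CT", "HU")
    pet = VolumetricImage(pet_vals, spacing, "PET", "SUV")
    return ct, pet, RegionMask(mask, spacing)


# ---------------------------------------------------------------------------
# Cohort


def effect_sizes_for_auc(target_auc: float, k: int) -> np.ndarray:
    """Equal per-feature standardized shifts giving a Bayes AUC of target_auc.

    For k independent informative features, AUC = Phi(||d|| / sqrt(2)),
    so each of the k features gets d = sqrt(2) * Phi^-1(auc) / sqrt(k).
    """
    if not (0.5 <= target_auc < 1.0):
        raise InvalidArgumentError("target AUC must be in [0.5, 1)")
    delta = np.sqrt(2.0) * ndtri(target_auc)
    return np.full(k, delta / np.sqrt(k))


def stratified_split(
    labels: np.ndarray, validation_fraction: float = 0.2, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Label-stratified split; per class round(n * fraction) go to validation."""
    labels = np.asarray(labels, dtype=int)
    rng = rng or np.random.default_rng(0)
    val = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        n_val = int(round(len(idx) * validation_fraction))
        val.extend(rng.permutation(idx)[:n_val].tolist())
    val = np.sort(np.array(val, dtype=int))
    train = np.setdiff1d(np.arange(len(labels)), val)
    return train, val


@dataclass
class CohortSpec:
    """Study-condition parameters for the synthetic cohort generator."""

    n_patients: int = 328
    prevalence: float = 0.21
    n_features_per_modality: int = 50
    n_informative: int = 5
    bayes_auc: float = 0.9  # per-modality Bayes-optimal AUC of the planted signal
    informative_effects: dict | None = None  # modality -> effect-size array
    signal_overlap: float = 0.0  # shared latent fraction between CT and PET signal
    clinical_effect: float = 0.6  # latent shift of ordinal covariates in positives
    censoring_rate: float = 0.1  # extra early censoring among positives
    event_median_months: float = 12.0
    followup_months: tuple[float, float] = (9.0, 113.0)
    block_size: int = 10
    block_rho: float = 0.6
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 10 or not (0 < self.prevalence < 1):
            raise InvalidArgumentError("need n >= 10 and prevalence in (0, 1)")
        if self.n_informative > self.n_features_per_modality:
            raise InvalidArgumentError("more informative features than features")
        if not (0 <= self.signal_overlap <= 1):
            raise InvalidArgumentError("signal overlap must be in [0, 1]")
        n_pos = int(round(self.n_patients * self.prevalence))
        if n_pos < 2 or self.n_patients - n_pos < 2:
            raise InvalidArgumentError("each class needs at least 2 patients")

    def effects(self, modality: str) -> np.ndarray:
        if self.informative_effects and modality in self.informative_effects:
            return np.asarray(self.informative_effects[modality], dtype=float)
        if self.bayes_auc <= 0.5:
            return np.zeros(self.n_informative)
        return effect_sizes_for_auc(self.bayes_auc, self.n_informative)


@dataclass
class SyntheticCohort:
    """Feature tables, clinical covariates, survival records and the split."""

    spec: CohortSpec
    tables: dict  # modality -> FeatureTable (clinical already encoded)
    clinical_raw: pd.DataFrame
    survival: list
    train_idx: np.ndarray
    val_idx: np.ndarray
    informative: dict  # modality -> list of planted feature names

    @property
    def labels(self) -> np.ndarray:
        return self.tables["CT"].labels

    def train_tables(self) -> dict:
        return {m: t.subset_rows(self.train_idx) for m, t in self.tables.items()}

    def val_tables(self) -> dict:
        return {m: t.subset_rows(self.val_idx) for m, t in self.tables.items()}

    def survival_subset(self, idx: np.ndarray) -> list:
        return [self.survival[i] for i in idx]


_SITE_P = {"Oropharynx": 0.674, "Nasopharynx": 0.192, "Oral cavity": 0.095, "Larynx": 0.039}
_SMOKING_P = {"Former": 0.482, "Never": 0.335, "Current": 0.183}
_HPV_P = {"Unknown": 0.470, "Negative": 0.305, "Positive": 0.225}


def _ordinal_from_latent(z: np.ndarray, probs: list[float]) -> np.ndarray:
    """Map standard-normal latents to ordinal codes with given base frequencies."""
    cuts = norm.ppf(np.cumsum(probs[:-1]))
    return np.searchsorted(cuts, z, side="right")


def _clinical_frame(
    rng: np.random.Generator, y: np.ndarray, effect: float
) -> pd.DataFrame:
    n = len(y)
    age = rng.normal(66.4, 10.4, n) + 1.5 * effect * y
    sex = rng.choice(["Male", "Female"], n, p=[0.796, 0.204])
    site = rng.choice(list(_SITE_P), n, p=list(_SITE_P.values()))
    smoking = rng.choice(list(_SMOKING_P), n, p=list(_SMOKING_P.values()))
    # ordinal stage/grade: latent shifted upward in positives
    t_cat = _ordinal_from_latent(rng.normal(0, 1, n) + effect * y,
                                 [0.19, 0.34, 0.25, 0.22])  # T1..T4
    n_cat = _ordinal_from_latent(rng.normal(0, 1, n) + effect * y,
                                 [0.19, 0.18, 0.59, 0.04])  # N0..N3
    grade = _ordinal_from_latent(rng.normal(0, 1, n) + 0.3 * effect * y,
                                 [0.05, 0.51, 0.44])  # low/intermediate/high
    # recurrence is enriched among HPV-negative patients
    hpv = np.array([
        rng.choice(list(_HPV_P), p=_tilt_hpv(effect if yi else 0.0)) for yi in y
    ])
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "site": site,
            "smoking": smoking,
            "t_stage": t_cat + 1,
            "n_stage": n_cat,
            "grade": grade + 1,
            "hpv": hpv,
        }
    )


def _tilt_hpv(effect: float) -> list[float]:
    w = np.array(list(_HPV_P.values()))
    w = w * np.array([1.0, np.exp(0.8 * effect), np.exp(-0.8 * effect)])
    return (w / w.sum()).tolist()


def encode_clinical(df: pd.DataFrame, labels: np.ndarray, patient_ids: list[str]) -> FeatureTable:
    """Numeric encoding: ordinal stage/grade, indicators for nominal categories."""
    cols: dict[str, np.ndarray] = {"age": df["age"].to_numpy(float)}
    cols["t_stage"] = df["t_stage"].to_numpy(float)
    cols["n_stage"] = df["n_stage"].to_numpy(float)
    cols["grade"] = df["grade"].to_numpy(float)
    cols["sex_male"] = (df["sex"] == "Male").to_numpy(float)
    for s in _SITE_P:
        cols[f"site_{s.split()[0].lower()}"] = (df["site"] == s).to_numpy(float)
    for s in _SMOKING_P:
        cols[f"smoking_{s.lower()}"] = (df["smoking"] == s).to_numpy(float)
    for s in _HPV_P:
        cols[f"hpv_{s.lower()}"] = (df["hpv"] == s).to_numpy(float)
    names = list(cols)
    values = np.stack([cols[c] for c in names], axis=1)
    return FeatureTable(patient_ids, names, values, labels, modality="clinical")


def _radiomic_table(
    rng: np.random.Generator,
    shared_signal: np.ndarray,
    y: np.ndarray,
    spec: CohortSpec,
    modality: str,
    patient_ids: list[str],
) -> tuple[FeatureTable, list[str]]:
    n, p = len(y), spec.n_features_per_modality
    effects = spec.effects(modality)
    k = len(effects)
    X = np.empty((n, p))
    # block-correlated nuisance features (radiomic redundancy)
    for start in range(0, p, spec.block_size):
        width = min(spec.block_size, p - start)
        z = rng.normal(0, 1, n)[:, None]
        eps = rng.normal(0, 1, (n, width))
        X[:, start:start + width] = (
            np.sqrt(spec.block_rho) * z + np.sqrt(1 - spec.block_rho) * eps
        )
    # planted informative features overwrite k random columns
    info_idx = np.sort(rng.choice(p, size=k, replace=False))
    ov = spec.signal_overlap
    own = rng.normal(0, 1, (n, k))
    latent = np.sqrt(ov) * shared_signal[:, :k] + np.sqrt(1 - ov) * own
    X[:, info_idx] = latent + effects[None, :] * y[:, None]
    names = [f"{modality}_f{j:03d}" for j in range(p)]
    table = FeatureTable(patient_ids, names, X, y, modality=modality)
    return table, [names[j] for j in info_idx]


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Simulate the full study cohort from a :class:`CohortSpec`.

    Reproducible from ``spec.seed``.  The default spec gives 328 patients
    (69 positive), split 262/66 by label-stratified 4:1 sampling.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    n_pos = int(round(n * spec.prevalence))
    y = np.zeros(n, dtype=int)
    y[rng.choice(n, size=n_pos, replace=False)] = 1
    ids = [f"P{i:04d}" for i in range(n)]

    shared = rng.normal(0, 1, (n, max(spec.n_informative, 1)))
    ct, info_ct = _radiomic_table(rng, shared, y, spec, "CT", ids)
    pet, info_pet = _radiomic_table(rng, shared, y, spec, "PET", ids)
    clin_raw = _clinical_frame(rng, y, spec.clinical_effect)
    clinical = encode_clinical(clin_raw, y, ids)

    # survival: positives experience local P/R (exponential times), negatives
    # are censored at last follow-up; censoring_rate cuts a fraction of the
    # positive events short before they are observed
    scale = spec.event_median_months / np.log(2.0)
    lo, hi = spec.followup_months
    times = np.empty(n)
    events = np.zeros(n, dtype=int)
    for i in range(n):
        if y[i] == 1:
            t_event = max(rng.exponential(scale), 0.25)
            if rng.random() < spec.censoring_rate:
                times[i] = max(0.25, rng.uniform(0.1, 1.0) * t_event)
                events[i] = 0
            else:
                times[i] = t_event
                events[i] = 1
        else:
            times[i] = rng.uniform(lo, hi)
            events[i] = 0
    survival = [SurvivalRecord(ids[i], float(times[i]), int(events[i])) for i in range(n)]

    train_idx, val_idx = stratified_split(y, spec.validation_fraction, rng)
    return SyntheticCohort(
        spec=spec,
        tables={"CT": ct, "PET": pet, "clinical": clinical},
        clinical_raw=clin_raw,
        survival=survival,
        train_idx=train_idx,
        val_idx=val_idx,
        informative={"CT": info_ct, "PET": info_pet},
    )
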