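"""Multi-objective, multi-classifier model core.

One candidate model ("solution") is a triple (f, beta, omega): a binary
feature-selection vector, a hyperparameter assignment for the three base
classifiers (logistic regression, shrinkage discriminant analysis, RBF
SVM), and classifier-fusion weights on the 3-simplex.  Each solution is
scored on the training cohort by three simultaneously maximized
objectives — sensitivity, specificity and feature sparsity (one over the
number of selected features, minimum one feature).

An iterative multi-objective immune algorithm (IMIA) evolves a population
of solutions: each generation clones the non-dominated members
proportionally to a crowding-distance affinity, hypermutates the clones
(bit flips on f, Gaussian steps on log-scale hyperparameters, a Dirichlet
blend on omega), and keeps the Pareto front plus diverse dominated members.
The archive of all non-dominated solutions found is fused into one
per-modality model: each archived solution gets a weight favouring
balanced sensitivity/specificity, and their probability outputs are
combined by the evidential-reasoning rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .classifiers import (
    BETA_RANGES,
    Beta,
    ZScaler,
    classifier_from_dict,
    CLASSIFIER_TYPES,
)
from .er import er_fuse_rows
from .errors import DegenerateFitError, InvalidArgumentError
from .metrics import confusion_metrics, roc_auc
from .tables import FeatureTable

__all__ = [
    "ObjectiveTriple",
    "Solution",
    "IMIAConfig",
    "fit_base_classifiers",
    "predict_solution",
    "evaluate_objectives",
    "dominates",
    "pareto_front",
    "crowding_distance",
    "hypervolume_3d",
    "imia_optimize",
    "solution_weights",
    "fuse_archive",
    "train_modality",
    "TrainedModalityModel",
]

_LOG_SCALE_KEYS = ("lr_c", "svm_c", "svm_gamma")


class ObjectiveTriple(NamedTuple):
    sensitivity: float
    specificity: float
    sparsity: float


@dataclass
class Solution:
    """One candidate model: feature mask, hyperparameters, classifier weights."""

    f: np.ndarray  # boolean over the pre-selected features
    beta: Beta
    omega: np.ndarray  # weights over (lr, da, svm), non-negative, sum 1
    objectives: ObjectiveTriple | None = None
    classifiers: dict | None = None  # kind -> fitted wrapper
    train_probs: np.ndarray | None = None  # fused classifier output on training rows

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=bool)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.f.sum() < 1:
            raise InvalidArgumentError("at least one feature must be selected")
        if self.omega.shape != (3,) or np.any(self.omega < -1e-9):
            raise InvalidArgumentError("omega must be 3 non-negative weights")
        s = self.omega.sum()
        if not math.isclose(s, 1.0, rel_tol=0, abs_tol=1e-6):
            raise InvalidArgumentError("omega must sum to 1")

    @property
    def n_selected(self) -> int:
        return int(self.f.sum())

    def identity_key(self) -> tuple:
        return (
            self.f.tobytes(),
            tuple(round(v, 12) for v in (self.beta.lr_c, self.beta.da_shrinkage,
                                         self.beta.svm_c, self.beta.svm_gamma)),
            tuple(round(v, 12) for v in self.omega),
        )


_CLF_ORDER = ("lr", "da", "svm")


def fit_base_classifiers(
    table: FeatureTable,
    f: np.ndarray,
    beta: Beta,
    classifiers: Sequence[str] = _CLF_ORDER,
    X_scaled: np.ndarray | None = None,
) -> dict:
    """Fit the enabled base classifiers on the f-selected, z-scored columns.

    Returns kind -> fitted wrapper.  Raises :class:`DegenerateFitError`
    for singular/degenerate fits (callers mark the solution infeasible).
    """
    f = np.asarray(f, dtype=bool)
    if f.sum() < 1:
        raise InvalidArgumentError("need at least one selected feature")
    if X_scaled is None:
        X_scaled = ZScaler().fit(table.values).transform(table.values)
    X = X_scaled[:, f]
    y = table.labels
    if np.all(X.std(axis=0) == 0):
        raise DegenerateFitError("selected features are all constant")
    fitted = {}
    for kind in classifiers:
        if kind == "lr":
            fitted["lr"] = CLASSIFIER_TYPES["lr"](C=beta.lr_c).fit(X, y)
        elif kind == "da":
            fitted["da"] = CLASSIFIER_TYPES["da"](shrinkage=beta.da_shrinkage).fit(X, y)
        elif kind == "svm":
            fitted["svm"] = CLASSIFIER_TYPES["svm"](C=beta.svm_c, gamma=beta.svm_gamma).fit(X, y)
        else:
            raise InvalidArgumentError(f"unknown classifier {kind!r}")
    return fitted


def predict_solution(fitted: dict, omega: np.ndarray, X_selected: np.ndarray) -> np.ndarray:
    """Classifier-fusion probability p = sum_c omega_c p_c(x) for each row."""
    omega = np.asarray(omega, dtype=float)
    p = np.zeros(np.atleast_2d(X_selected).shape[0])
    for k, kind in enumerate(_CLF_ORDER):
        if omega[k] > 0:
            p += omega[k] * fitted[kind].predict_proba_pos(X_selected)
    return np.clip(p, 0.0, 1.0)


def evaluate_objectives(
    solution: Solution, table: FeatureTable, threshold: float = 0.5
) -> ObjectiveTriple:
    """Training-cohort sensitivity/specificity at the threshold plus sparsity."""
    if solution.train_probs is None:
        raise InvalidArgumentError("solution has no cached training probabilities")
    sens, spec, _ = confusion_metrics(solution.train_probs, table.labels, threshold)
    return ObjectiveTriple(sens, spec, 1.0 / solution.n_selected)


# ---------------------------------------------------------------------------
# Pareto machinery


def dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """True iff a >= b component-wise with at least one strict improvement."""
    a = tuple(a)
    b = tuple(b)
    return all(x >= y for x, y in zip(a, b)) and any(x > y for x, y in zip(a, b))


def pareto_front(solutions: Sequence[Solution]) -> list[Solution]:
    """Exactly the non-dominated members, deduplicated by (f, beta, omega)."""
    if not solutions:
        raise InvalidArgumentError("pareto_front requires at least one solution")
    seen: dict[tuple, Solution] = {}
    for s in solutions:
        seen.setdefault(s.identity_key(), s)
    unique = list(seen.values())
    objs = [s.objectives for s in unique]
    front = []
    for i, s in enumerate(unique):
        if not any(dominates(objs[j], objs[i]) for j in range(len(unique)) if j != i):
            front.append(s)
    return front


def crowding_distance(objectives: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance; boundary points get the largest finite value."""
    objs = np.asarray(objectives, dtype=float)
    n, m = objs.shape
    if n <= 2:
        return np.ones(n)
    dist = np.zeros(n)
    big = 0.0
    for k in range(m):
        order = np.argsort(objs[:, k], kind="stable")
        rng = objs[order[-1], k] - objs[order[0], k]
        if rng == 0:
            continue
        gaps = (objs[order[2:], k] - objs[order[:-2], k]) / rng
        dist[order[1:-1]] += gaps
        big += 2.0
        dist[order[0]] = dist[order[-1]] = np.inf
    if not np.isfinite(dist).all():
        finite_max = dist[np.isfinite(dist)].max(initial=1.0)
        dist[~np.isfinite(dist)] = finite_max + max(big, 1.0)
    if dist.max() == 0:
        return np.ones(n)
    return dist


def hypervolume_3d(points: np.ndarray, reference=(0.0, 0.0, 0.0)) -> float:
    """Exact hypervolume of maximization points against a reference corner."""
    pts = np.asarray(points, dtype=float) - np.asarray(reference, dtype=float)
    pts = pts[np.all(pts > 0, axis=1)]
    if len(pts) == 0:
        return 0.0
    order = np.argsort(-pts[:, 0], kind="stable")
    pts = pts[order]
    hv = 0.0
    for i in range(len(pts)):
        x_hi = pts[i, 0]
        x_lo = pts[i + 1, 0] if i + 1 < len(pts) else 0.0
        if x_hi == x_lo:
            continue
        hv += (x_hi - x_lo) * _union_area_2d(pts[: i + 1, 1:])
    return hv


def _union_area_2d(rects: np.ndarray) -> float:
    """Union area of origin-anchored rectangles with corners (y_i, z_i)."""
    order = np.argsort(-rects[:, 0], kind="stable")
    area = 0.0
    z_cov = 0.0
    for y, z in rects[order]:
        if z > z_cov:
            area += y * (z - z_cov)
            z_cov = z
    return area


# ---------------------------------------------------------------------------
# IMIA


@dataclass
class IMIAConfig:
    """Optimizer settings; defaults reflect the study configuration
    (generation cap 50) with reconstructed immune-operator internals."""

    population_size: int = 50
    generations: int = 50
    clone_factor: float = 2.0
    p_flip: float | None = None  # default 2 / n_features
    sigma_log: float = 0.2  # Gaussian step on log10 hyperparameters
    sigma_shrinkage: float = 0.1  # DA shrinkage is bounded, stepped linearly
    omega_blend: float = 0.5  # mixing of omega with a fresh Dirichlet draw
    init_density: float = 0.15  # expected fraction of bits set at init
    include_sparsity: bool = True
    classifiers: tuple[str, ...] = ("lr", "da", "svm")
    fixed_beta: Beta | None = None
    fixed_omega: tuple[float, float, float] | None = None
    archive_max: int = 200
    hv_tol: float = 1e-9
    patience: int = 10
    threshold: float = 0.5
    # objective estimation: 1 = resubstitution on the training cohort (the
    # study's stated behaviour); >= 2 = internal stratified k-fold
    # out-of-fold estimates of sensitivity/specificity (optional mode)
    objective_cv: int = 1

    def validate(self, n_features: int) -> None:
        if self.population_size < 2 or self.generations < 1:
            raise InvalidArgumentError("population >= 2 and generations >= 1 required")
        if self.clone_factor <= 0 or not (0 < self.init_density <= 1):
            raise InvalidArgumentError("clone_factor > 0 and init_density in (0,1] required")
        if not self.classifiers or any(c not in _CLF_ORDER for c in self.classifiers):
            raise InvalidArgumentError("classifiers must be a subset of (lr, da, svm)")
        if n_features < 1:
            raise InvalidArgumentError("table must have at least one feature")


def _objective_vector(obj: ObjectiveTriple, include_sparsity: bool) -> tuple:
    if include_sparsity:
        return tuple(obj)
    return (obj.sensitivity, obj.specificity)


class _Evaluator:
    """Fits classifiers once per (f, beta) and caches per-classifier outputs.

    omega only mixes the cached probability columns, so re-weighted clones
    cost almost nothing.  With ``objective_cv >= 2`` the objective
    probabilities are stratified out-of-fold estimates; the classifiers
    kept on the solution are always fitted on the full training cohort.
    """

    def __init__(self, table: FeatureTable, config: IMIAConfig):
        self.table = table
        self.config = config
        self.scaler = ZScaler().fit(table.values)
        self.X = self.scaler.transform(table.values)
        self._folds = None
        if config.objective_cv >= 2:
            from sklearn.model_selection import StratifiedKFold

            skf = StratifiedKFold(n_splits=config.objective_cv, shuffle=False)
            self._folds = list(skf.split(self.X, table.labels))
        self._cache: dict[tuple, dict | None] = {}

    def _fit_key(self, sol: Solution) -> tuple:
        b = sol.beta
        return (sol.f.tobytes(), round(b.lr_c, 12), round(b.da_shrinkage, 12),
                round(b.svm_c, 12), round(b.svm_gamma, 12))

    def _fit_entry(self, sol: Solution) -> dict | None:
        try:
            fitted = fit_base_classifiers(
                self.table, sol.f, sol.beta, self.config.classifiers, self.X
            )
        except DegenerateFitError:
            return None
        Xs = self.X[:, sol.f]
        probs = {k: c.predict_proba_pos(Xs) for k, c in fitted.items()}
        if self._folds is not None:
            oof = {k: np.empty(self.table.n_patients) for k in fitted}
            try:
                for tr, te in self._folds:
                    sub = FeatureTable(
                        [self.table.patient_ids[i] for i in tr],
                        list(self.table.feature_names),
                        self.table.values[tr],
                        self.table.labels[tr],
                        self.table.modality,
                    )
                    fold_fit = fit_base_classifiers(
                        sub, sol.f, sol.beta, self.config.classifiers, self.X[tr]
                    )
                    for k, c in fold_fit.items():
                        oof[k][te] = c.predict_proba_pos(Xs[te])
                probs = oof
            except DegenerateFitError:
                return None
        return {"fitted": fitted, "probs": probs}

    def evaluate(self, sol: Solution) -> Solution:
        key = self._fit_key(sol)
        if key not in self._cache:
            self._cache[key] = self._fit_entry(sol)
        entry = self._cache[key]
        if entry is None:  # infeasible: objectives all zero
            sol.classifiers = None
            sol.train_probs = np.zeros(self.table.n_patients)
            sol.objectives = ObjectiveTriple(0.0, 0.0, 0.0)
            return sol
        sol.classifiers = entry["fitted"]
        p = np.zeros(self.table.n_patients)
        for k, kind in enumerate(_CLF_ORDER):
            if sol.omega[k] > 0:
                p += sol.omega[k] * entry["probs"][kind]
        sol.train_probs = np.clip(p, 0.0, 1.0)
        sol.objectives = evaluate_objectives(sol, self.table, self.config.threshold)
        return sol


def _random_omega(rng: np.random.Generator, config: IMIAConfig) -> np.ndarray:
    if config.fixed_omega is not None:
        return np.asarray(config.fixed_omega, dtype=float)
    omega = np.zeros(3)
    active = [_CLF_ORDER.index(c) for c in config.classifiers]
    draw = rng.dirichlet(np.ones(len(active)))
    omega[active] = draw
    return omega


def _random_beta(rng: np.random.Generator, config: IMIAConfig) -> Beta:
    if config.fixed_beta is not None:
        return config.fixed_beta
    draws = {}
    for key in _LOG_SCALE_KEYS:
        lo, hi = BETA_RANGES[key]
        draws[key] = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
    draws["da_shrinkage"] = rng.uniform(*BETA_RANGES["da_shrinkage"])
    return Beta(**draws)


def _random_solution(rng: np.random.Generator, n_features: int, config: IMIAConfig) -> Solution:
    f = rng.random(n_features) < config.init_density
    if not f.any():
        f[rng.integers(n_features)] = True
    return Solution(f, _random_beta(rng, config), _random_omega(rng, config))


def _mutate(sol: Solution, rng: np.random.Generator, config: IMIAConfig) -> Solution:
    n = len(sol.f)
    p = config.p_flip if config.p_flip is not None else 2.0 / n
    f = sol.f ^ (rng.random(n) < p)
    if not f.any():
        f = f.copy()
        f[rng.integers(n)] = True

    if config.fixed_beta is not None:
        beta = config.fixed_beta
    else:
        vals = sol.beta.to_dict()
        for key in _LOG_SCALE_KEYS:
            vals[key] = 10 ** (np.log10(vals[key]) + rng.normal(0, config.sigma_log))
        vals["da_shrinkage"] += rng.normal(0, config.sigma_shrinkage)
        beta = Beta(**vals).clipped()

    if config.fixed_omega is not None:
        omega = np.asarray(config.fixed_omega, dtype=float)
    else:
        fresh = _random_omega(rng, config)
        omega = (1 - config.omega_blend) * sol.omega + config.omega_blend * fresh
        omega = np.clip(omega, 0, None)
        omega /= omega.sum()
    return Solution(f, beta, omega)


def _front(solutions: Sequence[Solution], include_sparsity: bool) -> list[Solution]:
    """Non-dominated members under the active objective set."""
    seen: dict[tuple, Solution] = {}
    for s in solutions:
        seen.setdefault(s.identity_key(), s)
    unique = list(seen.values())
    objs = [_objective_vector(s.objectives, include_sparsity) for s in unique]
    return [
        s
        for i, s in enumerate(unique)
        if not any(dominates(objs[j], objs[i]) for j in range(len(unique)) if j != i)
    ]


def _merge_archive(archive: list[Solution], new: list[Solution], config: IMIAConfig) -> list[Solution]:
    front = _front(archive + new, config.include_sparsity) if (archive or new) else []
    if len(front) > config.archive_max:
        objs = np.array([_objective_vector(s.objectives, config.include_sparsity)
                         for s in front], dtype=float)
        crowd = crowding_distance(objs)
        keep = np.argsort(-crowd, kind="stable")[: config.archive_max]
        front = [front[i] for i in sorted(keep)]
    return front


def imia_optimize(
    table: FeatureTable,
    config: IMIAConfig | None = None,
    seed: int = 0,
    history: list | None = None,
) -> list[Solution]:
    """Run the immune optimization loop; returns the final Pareto archive.

    Fully reproducible given the seed.  Stops at ``config.generations``
    (default 50) or once the archive hypervolume has changed by less than
    ``hv_tol`` for ``patience`` consecutive generations.  Passing a list as
    ``history`` records the archive hypervolume after each generation.
    """
    config = config or IMIAConfig()
    config.validate(table.n_features)
    rng = np.random.default_rng(seed)
    ev = _Evaluator(table, config)

    pop = [ev.evaluate(_random_solution(rng, table.n_features, config))
           for _ in range(config.population_size)]
    archive = _merge_archive([], pop, config)

    def _hv(arch: list[Solution]) -> float:
        pts = [_objective_vector(s.objectives, config.include_sparsity) for s in arch]
        if not config.include_sparsity:
            pts = [(a, b, 1.0) for a, b in pts]
        return hypervolume_3d(pts)

    hv_prev = _hv(archive)
    if history is not None:
        history.append(hv_prev)
    stall = 0

    for _ in range(config.generations):
        front = _front(pop, config.include_sparsity)
        objs = np.array([_objective_vector(s.objectives, config.include_sparsity)
                         for s in front], dtype=float)
        affinity = crowding_distance(objs)
        affinity = affinity / affinity.sum()
        total_clones = max(len(front), int(round(config.clone_factor * config.population_size)))
        counts = np.maximum(1, np.floor(affinity * total_clones).astype(int))
        clones = []
        for s, c in zip(front, counts):
            for _ in range(int(c)):
                clones.append(ev.evaluate(_mutate(s, rng, config)))

        archive = _merge_archive(archive, clones, config)
        merged = pop + clones
        new_front = _front(merged, config.include_sparsity)
        survivors = list(new_front[: config.population_size])
        if len(survivors) < config.population_size:
            front_keys = {id(s) for s in survivors}
            rest = [s for s in merged if id(s) not in front_keys]
            if rest:
                idx = rng.permutation(len(rest))[: config.population_size - len(survivors)]
                survivors.extend(rest[i] for i in idx)
        pop = survivors

        hv = _hv(archive)
        if history is not None:
            history.append(hv)
        if abs(hv - hv_prev) < config.hv_tol:
            stall += 1
            if stall >= config.patience:
                break
        else:
            stall = 0
        hv_prev = hv
    return archive


# ---------------------------------------------------------------------------
# Archive fusion


def solution_weights(archive: Sequence[Solution]) -> np.ndarray:
    """Weights favouring balanced sensitivity/specificity, normalized to 1.

    w_i proportional to [(sens_i + spec_i)/2] * [1 - |sens_i - spec_i|].
    An all-zero raw vector falls back to uniform weights.
    """
    if not archive:
        raise InvalidArgumentError("archive must be non-empty")
    raw = np.array([
        (s.objectives.sensitivity + s.objectives.specificity) / 2.0
        * (1.0 - abs(s.objectives.sensitivity - s.objectives.specificity))
        for s in archive
    ])
    raw = np.clip(raw, 0.0, None)
    if raw.sum() == 0:
        return np.full(len(archive), 1.0 / len(archive))
    return raw / raw.sum()


def fuse_archive(
    archive: Sequence[Solution], weights: np.ndarray, probs: np.ndarray
) -> np.ndarray:
    """ER-fuse per-solution probabilities (len(archive) x n rows)."""
    if len(archive) != len(weights):
        raise InvalidArgumentError("one weight per archived solution required")
    return er_fuse_rows(np.asarray(weights, dtype=float), np.atleast_2d(probs))


@dataclass
class TrainedModalityModel:
    """ER-fused Pareto archive for one modality, with its training summary."""

    modality: str
    feature_names: list[str]
    scaler: ZScaler
    archive: list[Solution]
    weights: np.ndarray
    training_metrics: dict = field(default_factory=dict)

    def solution_probs(self, X: np.ndarray) -> np.ndarray:
        """Per-solution fused-classifier probabilities, shape (n_solutions, n)."""
        Xs = self.scaler.transform(np.atleast_2d(np.asarray(X, dtype=float)))
        rows = []
        for s in self.archive:
            if s.classifiers is None:
                rows.append(np.full(Xs.shape[0], 0.5))
            else:
                rows.append(predict_solution(s.classifiers, s.omega, Xs[:, s.f]))
        return np.stack(rows)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """ER-fused probability of local persistence/recurrence per row."""
        return fuse_archive(self.archive, self.weights, self.solution_probs(X))

    def predict_table(self, table: FeatureTable) -> np.ndarray:
        if table.feature_names != self.feature_names:
            raise InvalidArgumentError("table features do not match the trained model")
        return self.predict_proba(table.values)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "feature_names": self.feature_names,
            "scaler": self.scaler.to_dict(),
            "weights": np.asarray(self.weights).tolist(),
            "training_metrics": self.training_metrics,
            "archive": [
                {
                    "f": np.flatnonzero(s.f).tolist(),
                    "n_features": len(s.f),
                    "beta": s.beta.to_dict(),
                    "omega": s.omega.tolist(),
                    "objectives": list(s.objectives),
                    "classifiers": None if s.classifiers is None else
                    {k: c.to_dict() for k, c in s.classifiers.items()},
                }
                for s in self.archive
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModalityModel":
        archive = []
        for sd in d["archive"]:
            f = np.zeros(sd["n_features"], dtype=bool)
            f[sd["f"]] = True
            sol = Solution(
                f,
                Beta.from_dict(sd["beta"]),
                np.array(sd["omega"]),
                objectives=ObjectiveTriple(*sd["objectives"]),
            )
            if sd["classifiers"] is not None:
                sol.classifiers = {k: classifier_from_dict(c)
                                   for k, c in sd["classifiers"].items()}
            archive.append(sol)
        return cls(
            modality=d["modality"],
            feature_names=list(d["feature_names"]),
            scaler=ZScaler.from_dict(d["scaler"]),
            archive=archive,
            weights=np.array(d["weights"]),
            training_metrics=dict(d["training_metrics"]),
        )


def train_modality(
    table: FeatureTable, config: IMIAConfig | None = None, seed: int = 0
) -> TrainedModalityModel:
    """Optimize, weight and fuse one modality's model on its training table.

    Radiomic tables are expected pre-selected (<= 50 features); clinical
    tables are used as-is.  Training sensitivity/specificity/accuracy/AUC
    of the ER-fused output at threshold 0.5 are recorded.
    """
    config = config or IMIAConfig()
    archive = imia_optimize(table, config, seed)
    weights = solution_weights(archive)
    scaler = ZScaler().fit(table.values)
    if "svm" in config.classifiers:
        Xs = scaler.transform(table.values)
        for s in archive:
            if s.classifiers is not None and "svm" in s.classifiers:
                s.classifiers["svm"].recalibrate_cv(Xs[:, s.f], table.labels)
    model = TrainedModalityModel(
        modality=table.modality,
        feature_names=list(table.feature_names),
        scaler=scaler,
        archive=archive,
        weights=weights,
    )
    fused = model.predict_proba(table.values)
    sens, spec, acc = confusion_metrics(fused, table.labels, config.threshold)
    model.training_metrics = {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "auc": roc_auc(fused, table.labels),
        "median_n_selected": float(np.median([s.n_selected for s in archive])),
        "n_solutions": len(archive),
    }
    return model
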