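"""Base classifiers (LR, DA, SVM) with serializable probability outputs.

Each wrapper fits via scikit-learn but predicts from plain coefficient
arrays, so a model round-trips through JSON to bit-identical predictions.
The SVM gets a Platt-style sigmoid fitted on its training decision values
(an effectively unregularized 1-D logistic fit) to turn margins into
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import expit
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .errors import DegenerateFitError

__all__ = ["Beta", "BETA_RANGES", "ZScaler", "LRClassifier", "DAClassifier",
           "SVMClassifier", "CLASSIFIER_TYPES", "classifier_from_dict"]

# hyperparameter search ranges (log-uniform except DA shrinkage)
BETA_RANGES = {
    "lr_c": (1e-3, 1e3),
    "svm_c": (1e-2, 1e3),
    "svm_gamma": (1e-4, 10.0),
    "da_shrinkage": (0.0, 1.0),
}


@dataclass(frozen=True)
class Beta:
    """One hyperparameter assignment for the three base classifiers."""

    lr_c: float = 1.0
    da_shrinkage: float = 0.1
    svm_c: float = 1.0
    svm_gamma: float = 0.1

    def clipped(self) -> "Beta":
        return Beta(
            lr_c=float(np.clip(self.lr_c, *BETA_RANGES["lr_c"])),
            da_shrinkage=float(np.clip(self.da_shrinkage, *BETA_RANGES["da_shrinkage"])),
            svm_c=float(np.clip(self.svm_c, *BETA_RANGES["svm_c"])),
            svm_gamma=float(np.clip(self.svm_gamma, *BETA_RANGES["svm_gamma"])),
        )

    def to_dict(self) -> dict:
        return {"lr_c": self.lr_c, "da_shrinkage": self.da_shrinkage,
                "svm_c": self.svm_c, "svm_gamma": self.svm_gamma}

    @classmethod
    def from_dict(cls, d: dict) -> "Beta":
        return cls(**d)


class ZScaler:
    """Column z-scoring with training-cohort statistics.

    Zero-variance columns keep std 1 (they carry no information but must
    not poison the transform); callers decide whether selecting only such
    columns makes a solution infeasible.
    """

    def __init__(self, mean: np.ndarray | None = None, std: np.ndarray | None = None):
        self.mean_ = None if mean is None else np.asarray(mean, dtype=float)
        self.std_ = None if std is None else np.asarray(std, dtype=float)

    def fit(self, X: np.ndarray) -> "ZScaler":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        std = X.std(axis=0)
        self.constant_ = std == 0
        self.std_ = np.where(self.constant_, 1.0, std)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.std_

    def to_dict(self) -> dict:
        return {"mean": self.mean_.tolist(), "std": self.std_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ZScaler":
        return cls(np.array(d["mean"]), np.array(d["std"]))


def _check_train(X: np.ndarray, y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise DegenerateFitError("both outcome classes required for fitting")
    if np.all(X.std(axis=0) == 0):
        raise DegenerateFitError("all selected features are constant")


class LRClassifier:
    """L2-regularized logistic regression; probability = expit(Xw + b)."""

    kind = "lr"

    def __init__(self, w=None, b=None, C: float = 1.0):
        self.C = float(C)
        self.w = None if w is None else np.asarray(w, dtype=float)
        self.b = None if b is None else float(b)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LRClassifier":
        _check_train(X, y)
        est = LogisticRegression(
            C=self.C, solver="lbfgs", max_iter=500, class_weight="balanced"
        )
        est.fit(X, y)
        self.w = est.coef_.ravel().copy()
        self.b = float(est.intercept_[0])
        return self

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        return expit(np.asarray(X, dtype=float) @ self.w + self.b)

    def to_dict(self) -> dict:
        return {"kind": "lr", "C": self.C, "w": self.w.tolist(), "b": self.b}

    @classmethod
    def from_dict(cls, d: dict) -> "LRClassifier":
        return cls(w=d["w"], b=d["b"], C=d["C"])


class DAClassifier:
    """Linear discriminant analysis with covariance shrinkage (lsqr solver).

    Binary LDA is linear in x; the positive-class probability is the
    logistic of the decision value.
    """

    kind = "da"

    def __init__(self, w=None, b=None, shrinkage: float = 0.1):
        self.shrinkage = float(shrinkage)
        self.w = None if w is None else np.asarray(w, dtype=float)
        self.b = None if b is None else float(b)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DAClassifier":
        _check_train(X, y)
        # uniform priors: the decision threshold 0.5 then balances the classes
        est = LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage=self.shrinkage, priors=[0.5, 0.5]
        )
        try:
            est.fit(X, y)
        except np.linalg.LinAlgError as exc:  # singular pooled covariance
            raise DegenerateFitError(str(exc)) from exc
        self.w = est.coef_.ravel().copy()
        self.b = float(est.intercept_[0])
        if not (np.all(np.isfinite(self.w)) and np.isfinite(self.b)):
            raise DegenerateFitError("non-finite discriminant coefficients")
        return self

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        return expit(np.asarray(X, dtype=float) @ self.w + self.b)

    def to_dict(self) -> dict:
        return {"kind": "da", "shrinkage": self.shrinkage,
                "w": self.w.tolist(), "b": self.b}

    @classmethod
    def from_dict(cls, d: dict) -> "DAClassifier":
        return cls(w=d["w"], b=d["b"], shrinkage=d["shrinkage"])


class SVMClassifier:
    """RBF support-vector machine with Platt-style sigmoid calibration.

    The decision function is reconstructed from stored support vectors,
    dual coefficients and intercept; the sigmoid p = expit(a*f(x) + c) is
    fitted on the training decision values.
    """

    kind = "svm"

    def __init__(self, C: float = 1.0, gamma: float = 0.1, sv=None, dual=None,
                 intercept=None, platt_a=None, platt_b=None):
        self.C = float(C)
        self.gamma = float(gamma)
        self.sv = None if sv is None else np.asarray(sv, dtype=float)
        self.dual = None if dual is None else np.asarray(dual, dtype=float)
        self.intercept = None if intercept is None else float(intercept)
        self.platt_a = None if platt_a is None else float(platt_a)
        self.platt_b = None if platt_b is None else float(platt_b)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SVMClassifier":
        _check_train(X, y)
        est = SVC(kernel="rbf", C=self.C, gamma=self.gamma, class_weight="balanced")
        est.fit(X, y)
        self.sv = est.support_vectors_.copy()
        self.dual = est.dual_coef_.ravel().copy()
        self.intercept = float(est.intercept_[0])
        f = self._decision(X)
        if f.std() == 0:
            raise DegenerateFitError("constant SVM decision values")
        platt = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000,
                                   class_weight="balanced")
        platt.fit(f.reshape(-1, 1), y)
        self.platt_a = float(platt.coef_[0, 0])
        self.platt_b = float(platt.intercept_[0])
        return self

    def recalibrate_cv(self, X: np.ndarray, y: np.ndarray, folds: int = 3) -> "SVMClassifier":
        """Refit the Platt sigmoid on out-of-fold decision values.

        Resubstitution decision values are biased away from the margin for
        the training points themselves, which skews the sigmoid; fitting it
        on stratified out-of-fold decisions restores calibration.
        """
        from sklearn.model_selection import StratifiedKFold

        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        oof = np.empty(len(y))
        try:
            for tr, te in StratifiedKFold(n_splits=folds, shuffle=False).split(X, y):
                est = SVC(kernel="rbf", C=self.C, gamma=self.gamma, class_weight="balanced")
                est.fit(X[tr], y[tr])
                oof[te] = est.decision_function(X[te])
        except ValueError:  # a fold lost one class: keep resubstitution Platt
            return self
        if oof.std() == 0:
            return self
        platt = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000,
                                   class_weight="balanced")
        platt.fit(oof.reshape(-1, 1), y)
        self.platt_a = float(platt.coef_[0, 0])
        self.platt_b = float(platt.intercept_[0])
        return self

    def _decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        K = np.exp(-self.gamma * cdist(X, self.sv, "sqeuclidean"))
        return K @ self.dual + self.intercept

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        return expit(self.platt_a * self._decision(X) + self.platt_b)

    def to_dict(self) -> dict:
        return {"kind": "svm", "C": self.C, "gamma": self.gamma,
                "sv": self.sv.tolist(), "dual": self.dual.tolist(),
                "intercept": self.intercept,
                "platt_a": self.platt_a, "platt_b": self.platt_b}

    @classmethod
    def from_dict(cls, d: dict) -> "SVMClassifier":
        return cls(C=d["C"], gamma=d["gamma"], sv=d["sv"], dual=d["dual"],
                   intercept=d["intercept"], platt_a=d["platt_a"], platt_b=d["platt_b"])


CLASSIFIER_TYPES = {"lr": LRClassifier, "da": DAClassifier, "svm": SVMClassifier}


def classifier_from_dict(d: dict):
    return CLASSIFIER_TYPES[d["kind"]].from_dict(d)
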