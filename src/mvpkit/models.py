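"""Uniform contract over the seven estimators.

Seven algorithms are exposed — SVM, KNN, logistic regression, Gaussian
naive Bayes, LDA, decision tree and random forest.  All solve two-class
classification; SVM, KNN, tree and forest additionally solve regression.
Estimator internals are delegated to scikit-learn (the SVM path is libsvm);
this module owns the defaults, the seeding, the decision-value conventions
and linear weight extraction.

Decision-value convention (classification).  Every classifier reports a
signed scalar whose sign is the predicted class (+1/-1) and whose magnitude
is its confidence, on a scale comparable across models:

=============  =====================================================
SVM            signed margin w.x + b (libsvm decision function)
logistic/NBC   2 * (P(class +1) - 0.5)          (bounded in [-1, 1])
LDA            signed linear discriminant value
KNN            (votes_plus - votes_minus) / k   (bounded in [-1, 1])
tree/forest    2 * (P(class +1) - 0.5) from leaf / vote fractions
=============  =====================================================

Exact ties (decision value 0) predict +1, deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .data_io import DataError

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "Prediction",
    "ALGORITHMS",
    "REGRESSION_CAPABLE",
    "make_model",
    "fit",
    "predict",
    "decision_values",
    "linear_weights",
    "has_linear_weights",
]

ALGORITHMS = ("svm", "knn", "logistic", "naive_bayes", "lda", "tree", "forest")
REGRESSION_CAPABLE = ("svm", "knn", "tree", "forest")

# GUI-style parameter names: c, g, d, r, nu, p (SVM), k (KNN), trees (RF)
_DEFAULTS: dict[str, dict] = {
    "svm": {"kernel": "linear", "c": 1.0, "g": 0.1, "d": 3, "r": 0.0,
            "nu": 0.5, "p": 0.1},
    "knn": {"k": 11},
    "logistic": {},
    "naive_bayes": {},
    "lda": {},
    "tree": {},
    "forest": {"trees": 500},
}


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str
    task: str  # "classify" | "regress"
    params: dict = field(default_factory=dict)


@dataclass
class TrainedModel:
    spec: ModelSpec
    estimator: object
    n_features: int


@dataclass(frozen=True)
class Prediction:
    """One test-sample outcome: label or value, confidence, probability."""

    label_or_value: float
    decision_value: float
    probability: float | None = None


def make_model(algorithm: str, task: str = "classify",
               overrides: dict | None = None) -> ModelSpec:
    """Build a ModelSpec with the printed defaults filled in.

    Defaults: C-SVC, linear kernel, c=1 (classification SVM); e-SVR, linear
    kernel, c=1, epsilon p=0.1 (regression SVM); k=11 neighbours; 500 trees.
    ``overrides`` replaces individual defaults; unknown parameter names are
    rejected.
    """
    if algorithm not in ALGORITHMS:
        raise DataError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    if task not in ("classify", "regress"):
        raise DataError(f"unknown task {task!r}")
    if task == "regress" and algorithm not in REGRESSION_CAPABLE:
        raise DataError(
            f"{algorithm} does not support regression; regression-capable "
            f"algorithms are {REGRESSION_CAPABLE}"
        )
    params = dict(_DEFAULTS[algorithm])
    for key, value in (overrides or {}).items():
        if key not in params:
            raise DataError(
                f"unknown parameter {key!r} for {algorithm}; "
                f"valid names: {sorted(params) or 'none'}"
            )
        params[key] = value
    return ModelSpec(algorithm, task, params)


def _build_estimator(spec: ModelSpec, seed: int | None):
    a, t, p = spec.algorithm, spec.task, spec.params
    if a == "svm":
        kw = dict(kernel=p["kernel"], C=p["c"], gamma=p["g"],
                  degree=int(p["d"]), coef0=p["r"])
        return SVC(**kw) if t == "classify" else SVR(epsilon=p["p"], **kw)
    if a == "knn":
        k = int(p["k"])
        return (KNeighborsClassifier(n_neighbors=k) if t == "classify"
                else KNeighborsRegressor(n_neighbors=k))
    if a == "logistic":
        return LogisticRegression(max_iter=10_000)
    if a == "naive_bayes":
        return GaussianNB()
    if a == "lda":
        # the SVD solver is well defined for singular within-class covariance
        return LinearDiscriminantAnalysis(solver="svd")
    if a == "tree":
        return (DecisionTreeClassifier(random_state=seed) if t == "classify"
                else DecisionTreeRegressor(random_state=seed))
    if a == "forest":
        n = int(p["trees"])
        return (RandomForestClassifier(n_estimators=n, random_state=seed)
                if t == "classify"
                else RandomForestRegressor(n_estimators=n, random_state=seed))
    raise DataError(f"unknown algorithm {a!r}")


def fit(spec: ModelSpec, X, y, seed: int | None = 0) -> TrainedModel:
    """Fit the specified estimator; deterministic given (X, y, spec, seed)."""
    X = np.asarray(getattr(X, "values", X), dtype=float)
    y = np.asarray(getattr(y, "values", y), dtype=float).ravel()
    if X.shape[0] != len(y):
        raise DataError("X rows must equal the number of labels")
    if spec.task == "classify":
        classes = np.unique(y)
        if len(classes) != 2 or set(classes) != {-1.0, 1.0}:
            raise DataError(
                "classification requires canonical +1/-1 labels with both "
                "classes present"
            )
    est = _build_estimator(spec, seed)
    est.fit(X, y)
    return TrainedModel(spec, est, X.shape[1])


def _positive_probability(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    proba = model.estimator.predict_proba(X)
    pos = int(np.flatnonzero(model.estimator.classes_ == 1.0)[0])
    return proba[:, pos]


def decision_values(model: TrainedModel, X) -> np.ndarray:
    """Signed decision values on the unified cross-model scale."""
    X = np.asarray(getattr(X, "values", X), dtype=float)
    if X.shape[1] != model.n_features:
        raise DataError(
            f"test data has {X.shape[1]} features, model was trained on "
            f"{model.n_features}"
        )
    a, t = model.spec.algorithm, model.spec.task
    if t == "regress":
        return np.asarray(model.estimator.predict(X), dtype=float)
    if a == "svm":
        return np.asarray(model.estimator.decision_function(X), dtype=float)
    if a == "lda":
        return np.asarray(model.estimator.decision_function(X), dtype=float)
    # probability/vote-based classifiers: 2 * (P(+1) - 0.5), bounded [-1, 1]
    return 2.0 * (_positive_probability(model, X) - 0.5)


def predict(model: TrainedModel, X) -> list[Prediction]:
    """Predict each row; classification labels come from the decision sign.

    sign(decision_value) is the predicted class, with the exact tie
    (decision value 0) resolved to +1 — the one global tie rule.
    """
    X = np.asarray(getattr(X, "values", X), dtype=float)
    dv = decision_values(model, X)
    if model.spec.task == "regress":
        return [Prediction(float(v), float(v)) for v in dv]
    probabilistic = model.spec.algorithm not in ("svm", "lda")
    probs = _positive_probability(model, X) if probabilistic else None
    out = []
    for i, v in enumerate(dv):
        label = 1.0 if v >= 0 else -1.0
        out.append(Prediction(label, float(v),
                              None if probs is None else float(probs[i])))
    return out


def has_linear_weights(model: TrainedModel | ModelSpec) -> bool:
    spec = model if isinstance(model, ModelSpec) else model.spec
    if spec.algorithm in ("logistic", "lda"):
        return True
    return spec.algorithm == "svm" and spec.params.get("kernel") == "linear"


def linear_weights(model: TrainedModel) -> tuple[np.ndarray, float]:
    """(w, b) of the affine decision score of a linear model.

    Available for linear-kernel SVM, logistic regression and LDA.  For SVM
    and LDA the decision value equals w.x + b exactly; for logistic
    regression (w, b) is the log-odds hyperplane, sign-consistent with the
    probability-based decision value.
    """
    if not has_linear_weights(model):
        raise DataError(
            f"weights undefined: {model.spec.algorithm} "
            f"({model.spec.params.get('kernel', 'n/a')} kernel) has no "
            "affine decision function"
        )
    est = model.estimator
    w = np.asarray(est.coef_, dtype=float).ravel()
    b = float(np.asarray(est.intercept_, dtype=float).ravel()[0])
    return w, b
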