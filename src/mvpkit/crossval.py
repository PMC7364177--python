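"""Cross-validation engine: per-fold preprocessing + model, metrics, ROC.

For each fold the preprocessing chain (Z-score, PCA, feature selection) is
fitted on the training split only, both splits are transformed, the model
is fitted on the transformed training split and the held-out fold is
predicted.  Every sample is predicted exactly once.

Classification performance is reported from the pooled confusion counts
across folds (sample-weighted); the unweighted mean of per-fold accuracies
is reported alongside, since the two differ when folds are uneven.
Regression performance ("prediction precision") is the Pearson correlation
of the pooled out-of-fold predictions with the true scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve as sk_roc_curve

from . import models as models_mod
from . import preprocess as pp
from .data_io import DataError, FoldAssignment, LabelVector
from .models import ModelSpec, Prediction

__all__ = [
    "ZScoreStep",
    "PCAStep",
    "SelectStep",
    "LassoStep",
    "Pipeline",
    "ConfusionCounts",
    "FoldResult",
    "CVResult",
    "random_folds",
    "run_cv",
    "confusion_metrics",
    "roc_auc",
    "prediction_precision",
]


# --------------------------------------------------------------------------
# pipeline description
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ZScoreStep:
    direction: str = "columns"


@dataclass(frozen=True)
class PCAStep:
    variance_threshold: float | None = 0.95
    n_components: int | None = None


@dataclass(frozen=True)
class SelectStep:
    """Filter selection by F-score or linear-model |weight| ranking."""

    amount: object = 1.0
    method: str = "fscore"  # "fscore" | "weight"
    model_spec: ModelSpec | None = None  # for "weight"; defaults to the pipeline model


@dataclass(frozen=True)
class LassoStep:
    config: pp.LassoConfig | None = None


@dataclass(frozen=True)
class Pipeline:
    """Ordered preprocessing steps followed by the estimator spec."""

    model: ModelSpec
    steps: tuple = ()

    @property
    def task(self) -> str:
        return self.model.task


def _fit_step(step, Xtr, Xte, labels_tr, pipeline: Pipeline, seed: int):
    """Fit one preprocessing step on the training split, transform both.

    Returns (Xtr, Xte, backproject) where backproject maps a weight vector
    in the step's output feature space back to its input feature space
    (used to express linear-model weights per original feature).
    """
    if isinstance(step, ZScoreStep):
        Xtr2, Xte2, params = pp.zscore_fit_apply(Xtr, Xte, step.direction)
        if step.direction == "rows":
            return Xtr2, Xte2, lambda w: w
        sigma = params.sigma

        def back_z(w, sigma=sigma):
            out = np.zeros_like(w)
            np.divide(w, sigma, out=out, where=sigma > 0)
            return out

        return Xtr2, Xte2, back_z
    if isinstance(step, PCAStep):
        params = pp.pca_fit(Xtr, step.variance_threshold, step.n_components)
        return (pp.pca_apply(params, Xtr), pp.pca_apply(params, Xte),
                lambda w, L=params.component_loadings: L @ w)
    if isinstance(step, (SelectStep, LassoStep)):
        if isinstance(step, SelectStep):
            if step.method == "fscore":
                scores = pp.fscore_rank(Xtr, labels_tr)
            elif step.method == "weight":
                spec = step.model_spec or pipeline.model
                scores = pp.weight_rank(Xtr, labels_tr, spec)
            else:
                raise DataError(f"unknown selection method {step.method!r}")
            sel = pp.select_features(scores, step.amount).selected
        else:
            config = step.config or pp.LassoConfig(seed=seed)
            sel = pp.lasso_select(Xtr, labels_tr, config).selected
        p_in = Xtr.shape[1]

        def back_sel(w, sel=sel, p_in=p_in):
            out = np.zeros(p_in)
            out[sel] = w
            return out

        return Xtr[:, sel], Xte[:, sel], back_sel
    raise DataError(f"unknown pipeline step {step!r}")


# --------------------------------------------------------------------------
# folds
# --------------------------------------------------------------------------

def random_folds(n_samples: int, K: int, labels=None, seed: int = 0
                 ) -> FoldAssignment:
    """Evenly divide samples into K random folds, stratified per class.

    Fold sizes differ by at most one; for two-class labels each class's
    per-fold counts also differ by at most one.  Deterministic given seed.
    """
    if K < 2:
        raise DataError("at least two folds are required")
    if K > n_samples:
        raise DataError(f"K={K} exceeds the {n_samples} samples")
    rng = np.random.default_rng(seed)
    fold_of = np.zeros(n_samples, dtype=int)
    y = None
    if labels is not None:
        lab = labels if isinstance(labels, LabelVector) else None
        if lab is not None and lab.kind == "classification":
            y = lab.values
        elif lab is None:
            y = np.asarray(labels).ravel()
    if y is None:
        order = rng.permutation(n_samples)
        sizes = np.full(K, n_samples // K)
        sizes[: n_samples % K] += 1
        start = 0
        for k in range(K):
            fold_of[order[start:start + sizes[k]]] = k + 1
            start += sizes[k]
        return FoldAssignment(fold_of, K)
    totals = np.zeros(K, dtype=int)
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        base, rem = divmod(len(idx), K)
        # extras go to the currently smallest folds (lowest index on ties)
        extra_folds = np.argsort(totals, kind="stable")[:rem]
        counts = np.full(K, base)
        counts[extra_folds] += 1
        start = 0
        for k in range(K):
            fold_of[idx[start:start + counts[k]]] = k + 1
            totals[k] += counts[k]
            start += counts[k]
    return FoldAssignment(fold_of, K)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.TN + other.TN,
                               self.FP + other.FP, self.FN + other.FN)


def _count(predicted: np.ndarray, actual: np.ndarray) -> ConfusionCounts:
    pos, neg = actual == 1.0, actual == -1.0
    return ConfusionCounts(
        TP=int(np.sum((predicted == 1.0) & pos)),
        TN=int(np.sum((predicted == -1.0) & neg)),
        FP=int(np.sum((predicted == 1.0) & neg)),
        FN=int(np.sum((predicted == -1.0) & pos)),
    )


def confusion_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy, sensitivity, specificity from confusion counts.

    accuracy = (TP+TN)/(TP+FN+TN+FP); sensitivity = TP/(TP+FN);
    specificity = TN/(TN+FP).  A metric with an empty denominator is
    reported as None (not available), never coerced to 0.
    """
    if counts.total == 0:
        raise DataError("confusion counts are all zero")
    accuracy = (counts.TP + counts.TN) / counts.total
    sensitivity = (counts.TP / (counts.TP + counts.FN)
                   if counts.TP + counts.FN > 0 else None)
    specificity = (counts.TN / (counts.TN + counts.FP)
                   if counts.TN + counts.FP > 0 else None)
    return {"accuracy": accuracy, "sensitivity": sensitivity,
            "specificity": specificity}


def roc_auc(decision_values, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and AUC from pooled decision values.

    Sweeps a threshold over the scores; with ties, AUC equals the pairwise
    concordance P(s+ > s-) + 0.5 * P(s+ = s-).
    """
    scores = np.asarray(decision_values, dtype=float).ravel()
    y = np.asarray(getattr(labels, "values", labels), dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise DataError("ROC requires both classes among the labels")
    fpr, tpr, _ = sk_roc_curve(y, scores, pos_label=1.0)
    return fpr, tpr, float(sk_auc(fpr, tpr))


def prediction_precision(predicted, actual) -> float:
    """Pearson r between pooled out-of-fold predictions and true scores."""
    p = np.asarray(predicted, dtype=float).ravel()
    a = np.asarray(getattr(actual, "values", actual), dtype=float).ravel()
    if len(p) != len(a):
        raise DataError("predicted and actual lengths differ")
    if len(p) < 3:
        raise DataError("prediction precision needs >=3 pairs")
    if np.std(p) == 0 or np.std(a) == 0:
        raise DataError("undefined correlation: zero variance")
    return float(sps.pearsonr(p, a)[0])


# --------------------------------------------------------------------------
# the engine
# --------------------------------------------------------------------------

@dataclass
class FoldResult:
    fold: int
    test_indices: np.ndarray
    predictions: list[Prediction]
    counts: ConfusionCounts | None
    metrics: dict
    weights: tuple[np.ndarray, float] | None


@dataclass
class CVResult:
    task: str
    per_fold: list[FoldResult]
    predicted: np.ndarray       # in original sample order
    actual: np.ndarray
    decision_values: np.ndarray
    counts: ConfusionCounts | None
    aggregate: dict
    mean_weights: np.ndarray | None

    @property
    def statistic(self) -> float:
        """Pooled accuracy (classification) or Pearson r (regression)."""
        key = "accuracy" if self.task == "classify" else "r"
        return self.aggregate[key]

    def roc(self) -> tuple[np.ndarray, np.ndarray, float]:
        if self.task != "classify":
            raise DataError("ROC is defined for classification only")
        return roc_auc(self.decision_values, self.actual)


def _per_fold_seed(seed: int, fold: int) -> int:
    return (int(seed) * 1_000_003 + fold) % (2**31)


def run_cv(data, labels: LabelVector, folds: FoldAssignment,
           pipeline: Pipeline, seed: int = 0,
           collect_weights: bool = True,
           eval_labels: LabelVector | None = None) -> CVResult:
    """Run the full per-fold pipeline; every sample predicted exactly once.

    ``eval_labels`` scores the out-of-fold predictions against a different
    reference than the training labels; the permutation engine uses it to
    train on shuffled labels while measuring chance accuracy against the
    true ones.  Defaults to the training labels.
    """
    X = np.asarray(getattr(data, "values", data), dtype=float)
    y = labels.values if isinstance(labels, LabelVector) else np.asarray(labels,
                                                                         float)
    if isinstance(folds, FoldAssignment):
        fa = folds
    else:
        fa = FoldAssignment(np.asarray(folds))
    if len(fa) != X.shape[0] or len(y) != X.shape[0]:
        raise DataError("data, labels and folds must have equal lengths")
    y_eval = y if eval_labels is None else np.asarray(
        getattr(eval_labels, "values", eval_labels), dtype=float).ravel()
    task = pipeline.task
    n = X.shape[0]
    predicted = np.empty(n)
    decision = np.empty(n)
    per_fold: list[FoldResult] = []
    fold_weights: list[np.ndarray] = []
    intercepts: list[float] = []
    want_w = collect_weights and models_mod.has_linear_weights(pipeline.model)

    for k in range(1, fa.K + 1):
        tr, te = fa.train_indices(k), fa.test_indices(k)
        if task == "classify" and len(np.unique(y[tr])) < 2:
            raise DataError(
                f"training split for fold {k} is missing a class"
            )
        Xtr, Xte = X[tr], X[te]
        ytr = (LabelVector("classification", y[tr]) if task == "classify"
               else LabelVector("regression", y[tr]))
        backprojectors = []
        for step in pipeline.steps:
            Xtr, Xte, back = _fit_step(step, Xtr, Xte, ytr, pipeline,
                                       _per_fold_seed(seed, k))
            backprojectors.append(back)
        model = models_mod.fit(pipeline.model, Xtr, ytr,
                               seed=_per_fold_seed(seed, k))
        preds = models_mod.predict(model, Xte)
        predicted[te] = [p.label_or_value for p in preds]
        decision[te] = [p.decision_value for p in preds]
        weights = None
        if want_w:
            w, b = models_mod.linear_weights(model)
            for back in reversed(backprojectors):
                w = back(w)
            weights = (w, b)
            fold_weights.append(w)
            intercepts.append(b)
        if task == "classify":
            counts = _count(predicted[te], y_eval[te])
            metrics = confusion_metrics(counts)
        else:
            counts, metrics = None, {}
        per_fold.append(FoldResult(k, te, preds, counts, metrics, weights))

    if task == "classify":
        pooled = _count(predicted, y_eval)
        aggregate = confusion_metrics(pooled)
        aggregate["accuracy_mean_over_folds"] = float(
            np.mean([f.metrics["accuracy"] for f in per_fold])
        )
    else:
        pooled = None
        aggregate = {"r": prediction_precision(predicted, y_eval)}
    mean_w = np.mean(fold_weights, axis=0) if fold_weights else None
    return CVResult(task, per_fold, predicted, y_eval.copy(), decision, pooled,
                    aggregate, mean_w)
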