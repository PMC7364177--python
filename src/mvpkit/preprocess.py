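"""Leakage-safe feature preprocessing: Z-scoring, PCA, feature selection.

Every transform here follows the same discipline: parameters are estimated
on the training split only and then applied unchanged to the test split.
Row-direction Z-scoring is the one exception by construction — each sample
is normalised with its own row statistics, so no cross-sample information
flows at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso, LassoCV, LinearRegression
from sklearn.model_selection import KFold, StratifiedKFold

from .data_io import DataError

__all__ = [
    "ZScoreParams",
    "PCAParams",
    "SelectionResult",
    "LassoConfig",
    "zscore_fit_apply",
    "pca_fit",
    "pca_apply",
    "fscore_rank",
    "weight_rank",
    "select_features",
    "lasso_select",
]


def _matrix(data) -> np.ndarray:
    """Accept a FeatureMatrix or a plain 2-D array."""
    values = getattr(data, "values", data)
    return np.asarray(values, dtype=float)


# --------------------------------------------------------------------------
# Z-score transform
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ZScoreParams:
    """Mean/SD used for the Z transform; None for row direction (per-row)."""

    m: np.ndarray | None
    sigma: np.ndarray | None
    direction: str  # "columns" | "rows"


def _zscore_rows(X: np.ndarray) -> np.ndarray:
    # each row is its own population -> ddof=0
    m = X.mean(axis=1, keepdims=True)
    s = X.std(axis=1, ddof=0, keepdims=True)
    out = np.zeros_like(X)
    np.divide(X - m, s, out=out, where=s > 0)
    return out


def zscore_fit_apply(train, test=None, direction: str = "columns"):
    """Z-transform Z=(x-m)/sigma fitted on the training split.

    direction="columns": per-feature mean/SD from the training data (sample
    SD, ddof=1), applied to both splits — test values are scaled by training
    statistics only.  direction="rows": each sample normalised independently
    with its own row mean/SD (population SD), so train and test are handled
    identically.  Constant features (sigma=0) map to 0 rather than NaN.

    Returns ``(train_z, test_z, params)``; ``test_z`` is None when no test
    split is given.
    """
    Xtr = _matrix(train)
    Xte = None if test is None else _matrix(test)
    if direction == "rows":
        params = ZScoreParams(None, None, "rows")
        return _zscore_rows(Xtr), None if Xte is None else _zscore_rows(Xte), params
    if direction != "columns":
        raise ValueError(f"unknown direction {direction!r}")
    if Xtr.shape[0] < 2:
        raise DataError("column-direction Z-scoring needs >=2 training samples")
    m = Xtr.mean(axis=0)
    s = Xtr.std(axis=0, ddof=1)
    params = ZScoreParams(m, s, "columns")

    def apply(X: np.ndarray) -> np.ndarray:
        out = np.zeros_like(X)
        np.divide(X - m, s, out=out, where=s > 0)
        return out

    return apply(Xtr), None if Xte is None else apply(Xte), params


# --------------------------------------------------------------------------
# PCA dimension reduction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAParams:
    """Training-data PCA basis applied to any later split."""

    mean: np.ndarray
    component_loadings: np.ndarray  # features x components, orthonormal cols
    explained_variance_fraction: np.ndarray
    n_kept: int


def pca_fit(train, variance_threshold: float | None = 0.95,
            n_components: int | None = None) -> PCAParams:
    """Fit PCA on the training split and pick how many components to keep.

    Default rule: keep the smallest n whose cumulative explained variance
    reaches the threshold (0.95), i.e. the top n explain >=95% and the top
    n-1 explain <95%.  An explicit ``n_components`` overrides the rule; it
    may not exceed min(n_train - 1, n_features), the rank cap of a centered
    matrix.
    """
    X = _matrix(train)
    n, p = X.shape
    if n < 2:
        raise DataError("PCA needs >=2 training samples")
    cap = min(n - 1, p)
    mean = X.mean(axis=0)
    Xc = X - mean
    # thin SVD of the centered data: loadings = right singular vectors
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = svals**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    frac = frac[:cap]
    Vt = Vt[:cap]
    if n_components is not None:
        if n_components < 1 or n_components > cap:
            raise DataError(
                f"n_components={n_components} out of range; the cap for this "
                f"training set is {cap}"
            )
        n_kept = int(n_components)
    else:
        tau = float(variance_threshold)
        cum = np.cumsum(frac)
        reached = np.flatnonzero(cum >= tau - 1e-12)
        n_kept = int(reached[0]) + 1 if len(reached) else cap
    return PCAParams(mean, Vt[:n_kept].T, frac[:n_kept], n_kept)


def pca_apply(params: PCAParams, data) -> np.ndarray:
    """Project (x - train_mean) onto the fitted component loadings."""
    X = _matrix(data)
    if X.shape[1] != params.component_loadings.shape[0]:
        raise DataError(
            f"data has {X.shape[1]} features but PCA was fitted on "
            f"{params.component_loadings.shape[0]}"
        )
    return (X - params.mean) @ params.component_loadings


# --------------------------------------------------------------------------
# feature ranking and selection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionResult:
    scores: np.ndarray
    selected: np.ndarray  # ordered feature indices
    amount_spec: object
    method: str


def fscore_rank(train, labels) -> np.ndarray:
    """Per-feature F score of a training-split F test against the target.

    Two-class labels: one-way ANOVA F = MS_between / MS_within with
    equal-variance pooling.  A feature identical in both classes scores 0;
    nonzero class separation with zero within-class variance scores +inf
    (ranked above every finite score).

    Continuous targets (regression): the univariate linear-regression F,
    (n-2) * r^2 / (1 - r^2) with r the feature-target Pearson correlation —
    the natural analogue for ranking voxels by association with a score.
    """
    X = _matrix(train)
    y = np.asarray(getattr(labels, "values", labels), dtype=float).ravel()
    kind = getattr(labels, "kind", None)
    classes = np.unique(y)
    if kind == "regression" or (kind is None and len(classes) > 2):
        n = len(y)
        if n < 3:
            raise DataError("regression F ranking needs >=3 training samples")
        yc = y - y.mean()
        Xc = X - X.mean(axis=0)
        sy = np.sqrt((yc**2).sum())
        sx = np.sqrt((Xc**2).sum(axis=0))
        denom = sx * sy
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (Xc * yc[:, None]).sum(axis=0) / denom
        r = np.where(denom > 0, r, 0.0)
        r2 = np.clip(r**2, 0.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (n - 2) * r2 / (1.0 - r2)
        return np.where(r2 < 1.0, F, np.inf)
    if len(classes) != 2:
        raise DataError("F-score ranking requires exactly two classes")
    Xa, Xb = X[y == classes[0]], X[y == classes[1]]
    na, nb = len(Xa), len(Xb)
    if na < 2 or nb < 2:
        raise DataError("each class needs >=2 training samples for the F test")
    grand = X.mean(axis=0)
    ssb = na * (Xa.mean(axis=0) - grand) ** 2 + nb * (Xb.mean(axis=0) - grand) ** 2
    ssw = ((Xa - Xa.mean(axis=0)) ** 2).sum(axis=0) + (
        (Xb - Xb.mean(axis=0)) ** 2
    ).sum(axis=0)
    msb = ssb / 1.0  # df_between = k - 1 = 1
    msw = ssw / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / msw
    F = np.where(msw > 0, F, np.where(msb > 0, np.inf, 0.0))
    return F


def weight_rank(train, labels, model_spec) -> np.ndarray:
    """|w_j| from a linear model fitted on the training split only."""
    from . import models  # local import: avoid a cycle at package init

    X = _matrix(train)
    y = np.asarray(getattr(labels, "values", labels), dtype=float).ravel()
    trained = models.fit(model_spec, X, y)
    w, _ = models.linear_weights(trained)
    return np.abs(w)


def select_features(scores, amount) -> SelectionResult:
    """Keep the top-scoring features.

    ``amount`` is an integer count or a fraction in (0, 1]; a fraction f
    keeps floor(f * n_features), at least 1.  Ties (including ties at +inf)
    break toward the lower feature index.  The kept set for n is always a
    prefix of the kept set for n+1.
    """
    scores = np.asarray(scores, dtype=float)
    p = len(scores)
    if isinstance(amount, float) and 0 < amount <= 1:
        # a float in (0, 1] is a fraction of the feature count
        count = max(1, math.floor(amount * p))
    elif float(amount).is_integer():
        count = int(amount)
    else:
        raise DataError(
            f"amount must be an integer count or a fraction in (0, 1], got {amount}"
        )
    if count < 1:
        raise DataError("amount must select at least one feature")
    if count > p:
        raise DataError(f"amount {count} exceeds the {p} available features")
    # stable sort on -scores: equal scores keep ascending index order
    order = np.argsort(-scores, kind="stable")
    return SelectionResult(scores, order[:count], amount,
                           method="score_ranking")


# --------------------------------------------------------------------------
# LASSO embedded selection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LassoConfig:
    """LASSO selection settings.

    The penalty weight lambda multiplies the L1 term of
    (1/2N) * sum (y_i - w0 - x_i.w)^2 + lambda * sum |w_j|.
    With ``lam`` unset, lambda is chosen from ``lambda_grid`` (default: 100
    values log-spaced from the data-derived lambda_max down to
    lambda_max * 1e-4) by 10-fold cross-validation within the training
    split, minimising mean squared error; inner folds are stratified for
    classification labels and derived deterministically from ``seed``.
    """

    lam: float | None = None
    lambda_grid: np.ndarray | None = None
    inner_folds: int = 10
    n_lambdas: int = 100
    grid_eps: float = 1e-4
    seed: int = 0


def _inner_cv(y: np.ndarray, config: LassoConfig, classification: bool):
    if classification:
        return StratifiedKFold(
            n_splits=config.inner_folds, shuffle=True, random_state=config.seed
        ).split(np.zeros_like(y), y)
    return KFold(
        n_splits=config.inner_folds, shuffle=True, random_state=config.seed
    ).split(np.zeros_like(y))


def lasso_select(train, labels, config: LassoConfig | None = None) -> SelectionResult:
    """Select the features with nonzero LASSO coefficients.

    Classification labels (+1/-1) are regressed on as numeric targets, the
    usual embedded-selection trick.  An empty selection at the chosen lambda
    is an error — no silent fallback to all features.
    """
    config = config or LassoConfig()
    X = _matrix(train)
    y = np.asarray(getattr(labels, "values", labels), dtype=float).ravel()
    kind = getattr(labels, "kind", "regression")
    if X.shape[0] < config.inner_folds and config.lam is None:
        raise DataError(
            f"LASSO inner CV needs >= {config.inner_folds} training samples"
        )
    if config.lam is not None:
        lam = float(config.lam)
        if lam == 0.0:
            coef = LinearRegression().fit(X, y).coef_
        else:
            coef = Lasso(alpha=lam, max_iter=50_000).fit(X, y).coef_
    else:
        splits = list(_inner_cv(y, config, kind == "classification"))
        if config.lambda_grid is not None:
            cv_model = LassoCV(alphas=np.asarray(config.lambda_grid, float),
                               cv=splits, max_iter=50_000)
        else:
            cv_model = LassoCV(alphas=config.n_lambdas, eps=config.grid_eps,
                               cv=splits, max_iter=50_000)
        cv_model.fit(X, y)
        lam, coef = float(cv_model.alpha_), cv_model.coef_
    selected = np.flatnonzero(coef != 0)
    if len(selected) == 0:
        raise DataError(
            "empty selection: all LASSO coefficients are zero at "
            f"lambda={lam:g}"
        )
    scores = np.abs(coef)
    order = np.argsort(-scores[selected], kind="stable")
    return SelectionResult(scores, selected[order], f"lasso(lambda={lam:g})",
                           method="lasso")
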