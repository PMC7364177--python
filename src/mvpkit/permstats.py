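"""Permutation-based inference with the <1/N convention and FWE correction.

The null distribution of the cross-validated statistic (pooled accuracy or
prediction precision) is built by shuffling the label/score vector, holding
the fold structure fixed, and re-running the entire pipeline — including any
training-fold feature selection or PCA — once per permutation.  The p-value
is the fraction of null statistics greater than or equal to the observed
one; when no null statistic reaches it, the result is reported as the bound
P < 1/N rather than P = 0.

For searchlight maps, family-wise error is controlled with the
max-statistic procedure: each permutation uses one shuffled label vector
for every sphere, only the per-permutation maximum across spheres is kept,
and every center's observed statistic is compared against that common
null distribution of maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import crossval, searchlight as sl
from .data_io import DataError, LabelVector

__all__ = [
    "PValue",
    "PermutationResult",
    "FWEResult",
    "pvalue",
    "permutation_test",
    "permutation_test_searchlight",
    "fwe_correct",
]


@dataclass(frozen=True)
class PValue:
    """count/N permutation p-value with the <1/N bound for zero counts."""

    count: int
    n: int

    @property
    def is_bound(self) -> bool:
        return self.count == 0

    @property
    def value(self) -> float:
        """count/N; 0.0 signals the bound P < 1/N (see ``is_bound``)."""
        return self.count / self.n

    def __str__(self) -> str:
        if self.is_bound:
            return f"P < {1 / self.n:g} (i.e., P < 1/{self.n})"
        return f"P = {self.value:g}"


def pvalue(observed: float, null_samples) -> PValue:
    """p = #{null >= observed} / N, with the P < 1/N bound at zero count."""
    null_samples = np.asarray(null_samples, dtype=float).ravel()
    if len(null_samples) == 0:
        raise DataError("empty null distribution")
    count = int(np.sum(null_samples >= observed))
    return PValue(count, len(null_samples))


def permutation_seed(seed: int, iteration: int) -> np.random.Generator:
    """Generator for one permutation, a pure function of (seed, iteration)."""
    return np.random.default_rng([int(seed), int(iteration)])


def _shuffled(labels: LabelVector, rng: np.random.Generator) -> LabelVector:
    values = rng.permutation(labels.values)
    return LabelVector(labels.kind, values)


@dataclass
class PermutationResult:
    observed: float
    null_samples: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return len(self.null_samples)

    @property
    def p(self) -> PValue:
        return pvalue(self.observed, self.null_samples)


def permutation_test(data, labels: LabelVector, folds, pipeline,
                     n_permutations: int, seed: int = 0) -> PermutationResult:
    """Null distribution of the CV statistic under label/score shuffling.

    Per iteration i the full label vector is permuted with a generator
    derived from (seed, i) and folds stay fixed; every fold's model (and any
    training-fold feature selection or PCA) is refitted on the shuffled
    labels, and the chance-level statistic scores the resulting predictions
    against the *true* labels — training with random labels, predicting the
    test samples.  The observed statistic is computed once with the true
    labels.  Fully deterministic given (seed, N), independent of execution
    order.
    """
    if n_permutations < 1:
        raise DataError("at least one permutation is required")
    observed = crossval.run_cv(data, labels, folds, pipeline, seed=seed,
                               collect_weights=False).statistic
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        shuffled = _shuffled(labels, permutation_seed(seed, i))
        try:
            null[i] = crossval.run_cv(data, shuffled, folds, pipeline,
                                      seed=seed, collect_weights=False,
                                      eval_labels=labels).statistic
        except DataError as exc:
            raise DataError(f"permutation {i} failed: {exc}") from exc
    return PermutationResult(float(observed), null, seed)


@dataclass
class FWEResult:
    """Max-statistic FWE correction over searchlight centers."""

    max_null: np.ndarray          # per-permutation maxima over centers
    corrected_counts: np.ndarray  # per-center #{max_null >= observed}
    n: int

    @property
    def corrected_p(self) -> np.ndarray:
        """count/N per center; 0 entries mean the bound P < 1/N."""
        return self.corrected_counts / self.n

    def pvalue_at(self, center: int) -> PValue:
        return PValue(int(self.corrected_counts[center]), self.n)


def fwe_correct(observed_map, permuted_maps) -> FWEResult:
    """Corrected p per center from the common max-over-centers null.

    ``permuted_maps`` has one row per permutation (computed with the same
    shuffled labels across all centers) and one column per center.
    """
    observed = np.asarray(observed_map, dtype=float).ravel()
    maps = np.asarray(permuted_maps, dtype=float)
    if maps.ndim != 2 or maps.shape[1] != len(observed):
        raise DataError(
            f"permuted maps of shape {maps.shape} do not match the "
            f"{len(observed)} observed centers"
        )
    max_null = np.nanmax(maps, axis=1)
    counts = (max_null[:, None] >= observed[None, :]).sum(axis=0)
    return FWEResult(max_null, counts.astype(int), maps.shape[0])


@dataclass
class SearchlightPermutationResult:
    observed_map: np.ndarray
    uncorrected_counts: np.ndarray
    fwe: FWEResult
    n: int

    @property
    def uncorrected_p(self) -> np.ndarray:
        return self.uncorrected_counts / self.n

    @property
    def corrected_p(self) -> np.ndarray:
        return self.fwe.corrected_p


def permutation_test_searchlight(data, labels: LabelVector, folds,
                                 radius: float, pipeline, n_permutations: int,
                                 seed: int = 0, units: str = "voxel",
                                 ) -> SearchlightPermutationResult:
    """Searchlight permutation inference with max-statistic FWE correction.

    Each permutation shuffles the labels once and re-runs the searchlight on
    every sphere with that same shuffled vector; per-center exceedance
    counts give uncorrected p-maps and the per-permutation maxima give the
    FWE-corrected p-maps.
    """
    index = sl.build_spheres(data.space, radius, units)
    observed = sl.run_searchlight(data, labels, folds, radius, pipeline,
                                  seed=seed, units=units,
                                  sphere_index=index).statistic_map
    n_centers = len(observed)
    unc = np.zeros(n_centers, dtype=int)
    max_null = np.empty(n_permutations)
    perm_rows = np.empty((n_permutations, n_centers))
    for i in range(n_permutations):
        shuffled = _shuffled(labels, permutation_seed(seed, i))
        row = sl.run_searchlight(data, shuffled, folds, radius, pipeline,
                                 seed=seed, units=units, sphere_index=index,
                                 eval_labels=labels).statistic_map
        perm_rows[i] = row
        with np.errstate(invalid="ignore"):
            unc += (row >= observed).astype(int)
        max_null[i] = np.nanmax(row)
    fwe = fwe_correct(observed, perm_rows)
    return SearchlightPermutationResult(observed, unc, fwe, n_permutations)
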