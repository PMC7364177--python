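"""Multimodal data fusion: feature concatenation and decision-level voting.

Two strategies.  *Concatenate* joins the feature blocks column-wise into one
matrix (optionally z-normalising each block to a comparable range first) and
runs a single cross-validation on it.  *Vote* trains one model per block
with identical folds and fuses the out-of-fold decisions per test sample:
for classification the fused score is the sum of the models' signed
decision values — each model's vote is weighted by its own confidence
|decision value| — and the fused label is the sign (tie at 0 -> +1); for
regression the fused prediction is the plain mean of the models' predicted
values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import crossval
from .crossval import CVResult, Pipeline
from .data_io import DataError, FeatureMatrix, LabelVector, TabularSpace

__all__ = ["FeatureBlock", "concatenate_features", "vote", "run_fusion"]


@dataclass
class FeatureBlock:
    """One feature type entering a fusion, with optional pre-normalisation."""

    name: str
    matrix: FeatureMatrix
    normalize: str = "none"  # "none" | "zscore"


def _normalized(block: FeatureBlock) -> np.ndarray:
    X = block.matrix.values
    if block.normalize == "none":
        return X
    if block.normalize == "zscore":
        # per-column z over all samples: a label-free range alignment
        m, s = X.mean(axis=0), X.std(axis=0, ddof=0)
        out = np.zeros_like(X)
        np.divide(X - m, s, out=out, where=s > 0)
        return out
    raise DataError(f"unknown normalize mode {block.normalize!r}")


def concatenate_features(blocks: list[FeatureBlock]) -> FeatureMatrix:
    """Join blocks column-wise; the fused space is tabular (geometry lost).

    A block -> column-range index is kept on the fused space so linear
    weights can be reported per block afterwards.
    """
    if not blocks:
        raise DataError("no blocks to concatenate")
    n = blocks[0].matrix.n_samples
    for b in blocks:
        if b.matrix.n_samples != n:
            raise DataError(
                f"sample-count mismatch: block {blocks[0].name!r} has {n} "
                f"samples, block {b.name!r} has {b.matrix.n_samples}"
            )
    parts, ranges, start = [], {}, 0
    for b in blocks:
        X = _normalized(b)
        parts.append(X)
        ranges[b.name] = (start, start + X.shape[1])
        start += X.shape[1]
    fused = np.hstack(parts)
    space = TabularSpace(fused.shape[1], block_ranges=ranges)
    return FeatureMatrix(fused, list(blocks[0].matrix.sample_ids), space)


def vote(decision_sets: dict[str, np.ndarray], task: str
         ) -> tuple[np.ndarray, np.ndarray]:
    """Fuse per-model decisions for the same samples.

    ``decision_sets`` maps model name -> per-sample decision values
    (classification, unified sign-coherent scale) or predicted values
    (regression).  Returns (fused_labels_or_values, fused_scores).
    """
    if len(decision_sets) < 2:
        raise DataError("voting needs at least two models")
    arrays = [np.asarray(v, dtype=float).ravel() for v in decision_sets.values()]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise DataError("mismatched sample sets across models")
    stacked = np.vstack(arrays)
    if task == "classify":
        fused_score = stacked.sum(axis=0)
        fused_label = np.where(fused_score >= 0, 1.0, -1.0)
        return fused_label, fused_score
    fused_value = stacked.mean(axis=0)
    return fused_value, fused_value


def run_fusion(blocks: list[FeatureBlock], labels: LabelVector, folds,
               pipeline: Pipeline | dict[str, Pipeline],
               strategy: str = "concatenate", seed: int = 0) -> CVResult:
    """Run a fused analysis end to end.

    strategy="concatenate": one cross-validation on the fused matrix.
    strategy="vote": one cross-validation per block with identical folds,
    then a confidence-weighted vote per test sample; ``pipeline`` may be a
    single Pipeline for all blocks or a per-block-name mapping.
    """
    if strategy == "concatenate":
        fused = concatenate_features(blocks)
        pipe = pipeline if isinstance(pipeline, Pipeline) else None
        if pipe is None:
            raise DataError("concatenate strategy takes a single pipeline")
        return crossval.run_cv(fused, labels, folds, pipe, seed=seed)
    if strategy != "vote":
        raise DataError(f"unknown fusion strategy {strategy!r}")

    def pipe_for(name: str) -> Pipeline:
        if isinstance(pipeline, Pipeline):
            return pipeline
        return pipeline[name]

    if len(blocks) < 2:
        raise DataError("voting needs at least two blocks")
    task = pipe_for(blocks[0].name).task
    results = {
        b.name: crossval.run_cv(b.matrix, labels, folds, pipe_for(b.name),
                                seed=seed, collect_weights=False)
        for b in blocks
    }
    decisions = {name: r.decision_values for name, r in results.items()}
    fused_pred, fused_score = vote(decisions, task)
    y = labels.values
    if task == "classify":
        counts = crossval._count(fused_pred, y)
        aggregate = crossval.confusion_metrics(counts)
    else:
        counts = None
        aggregate = {"r": crossval.prediction_precision(fused_pred, y)}
    return CVResult(task, [], fused_pred, y.copy(), fused_score, counts,
                    aggregate, None)
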