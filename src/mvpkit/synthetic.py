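"""Synthetic fixture generation: volume sets with controllable signal.

Generates the same NIfTI + delimited formats :mod:`mvpkit.data_io`
consumes, so every analysis path is exercisable without any download.  The
model is deliberately simple — i.i.d. Gaussian voxel noise with a
box-shaped mean shift (classification) or a box of score-proportional
signal (regression) — which is sufficient to exercise every pipeline path
while staying analytically tractable.  Optional isotropic smoothing adds
spatial autocorrelation; it is off by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from . import crossval
from .data_io import (DataError, FeatureMatrix, FoldAssignment, LabelVector,
                      VolumeSpace)

__all__ = [
    "FixtureSpec",
    "classification_dataset",
    "regression_dataset",
    "make_classification_volumes",
    "make_regression_volumes",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Study-condition parameters for one synthetic dataset.

    ``effect`` is the class mean shift inside ``signal_region`` in units of
    the noise SD; ``signal_region`` is an inclusive-exclusive voxel box
    ((x0, x1), (y0, y1), (z0, z1)).  For regression, voxels in the region
    follow regression_slope * (score - mid-range) + noise.
    """

    grid: tuple[int, int, int] = (8, 8, 8)
    n_per_class: int = 20
    n_subjects: int = 20
    signal_region: tuple = ((2, 5), (2, 5), (2, 5))
    effect: float = 5.0
    noise_sd: float = 1.0
    task: str = "classify"
    score_range: tuple[float, float] = (400.0, 700.0)
    regression_slope: float = 0.005
    n_folds: int = 10
    smooth_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise DataError("noise_sd must be positive")
        n = self.n_per_class * 2 if self.task == "classify" else self.n_subjects
        if n < 4:
            raise DataError("at least 4 samples are required")
        for (lo, hi), d in zip(self.signal_region, self.grid):
            if not (0 <= lo < hi <= d):
                raise DataError(
                    f"signal_region {self.signal_region} outside grid {self.grid}"
                )


def _region_mask(spec: FixtureSpec) -> np.ndarray:
    box = np.zeros(spec.grid, dtype=bool)
    (x0, x1), (y0, y1), (z0, z1) = spec.signal_region
    box[x0:x1, y0:y1, z0:z1] = True
    return box


def _space(spec: FixtureSpec) -> VolumeSpace:
    return VolumeSpace(dims=spec.grid, voxel_size=(1.0, 1.0, 1.0),
                       affine=np.eye(4), mask=np.ones(spec.grid, dtype=bool))


def _maybe_smooth(vol: np.ndarray, spec: FixtureSpec) -> np.ndarray:
    if spec.smooth_sigma > 0:
        return ndimage.gaussian_filter(vol, spec.smooth_sigma)
    return vol


def classification_dataset(spec: FixtureSpec):
    """In-memory classification fixture.

    Returns (volumes [n, x, y, z], labels, folds, space).  Class +1 samples
    carry a mean shift of effect * noise_sd inside the signal box; classes
    are balanced and folds stratified.  Fully determined by spec.seed.
    """
    if spec.task != "classify":
        raise DataError("spec.task must be 'classify'")
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_per_class
    box = _region_mask(spec)
    labels = np.r_[np.ones(spec.n_per_class), -np.ones(spec.n_per_class)]
    volumes = rng.normal(0.0, spec.noise_sd, size=(n, *spec.grid))
    volumes[labels == 1.0] += spec.effect * spec.noise_sd * box
    if spec.smooth_sigma > 0:
        volumes = np.stack([_maybe_smooth(v, spec) for v in volumes])
    folds = crossval.random_folds(n, spec.n_folds,
                                  LabelVector("classification", labels),
                                  seed=spec.seed)
    return volumes, LabelVector("classification", labels), folds, _space(spec)


def regression_dataset(spec: FixtureSpec):
    """In-memory regression fixture.

    Scores are Uniform(score_range); voxels inside the signal box follow
    regression_slope * (score - mid-range) plus noise, voxels outside are
    pure noise.  Returns (volumes, scores, folds, space).
    """
    if spec.task != "regress":
        raise DataError("spec.task must be 'regress'")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    box = _region_mask(spec)
    lo, hi = spec.score_range
    scores = rng.uniform(lo, hi, size=n)
    centered = scores - (lo + hi) / 2.0
    volumes = rng.normal(0.0, spec.noise_sd, size=(n, *spec.grid))
    volumes += spec.regression_slope * centered[:, None, None, None] * box
    if spec.smooth_sigma > 0:
        volumes = np.stack([_maybe_smooth(v, spec) for v in volumes])
    folds = crossval.random_folds(n, spec.n_folds, None, seed=spec.seed)
    return volumes, LabelVector("regression", scores), folds, _space(spec)


def as_feature_matrix(volumes: np.ndarray, space: VolumeSpace
                      ) -> FeatureMatrix:
    rows = [space.extract(v) for v in volumes]
    ids = [f"sample_{i:03d}" for i in range(len(rows))]
    return FeatureMatrix(np.vstack(rows), ids, space)


def _write_set(volumes, targets: LabelVector, folds: FoldAssignment,
               space: VolumeSpace, spec: FixtureSpec, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, vol in enumerate(volumes):
        img = nib.Nifti1Image(np.asarray(vol, dtype=np.float64), space.affine)
        path = out / f"sample_{i:03d}.nii.gz"
        nib.save(img, str(path))
        paths.append(path)
    mask_path = out / "mask.nii.gz"
    nib.save(nib.Nifti1Image(space.mask.astype(np.float64), space.affine),
             str(mask_path))
    label_path = out / ("labels.txt" if spec.task == "classify" else "scores.txt")
    np.savetxt(str(label_path), targets.values, fmt="%.10g")
    fold_path = out / "folds.txt"
    np.savetxt(str(fold_path), folds.fold_of_sample, fmt="%d")
    manifest = {"spec": asdict(spec), "n_samples": len(paths)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"volumes": paths, "mask": mask_path, "labels": label_path,
            "folds": fold_path, "manifest": out / "manifest.json"}


def make_classification_volumes(spec: FixtureSpec, out_dir) -> dict:
    """Write a classification volume set: per-sample NIfTI files, mask,
    labels column, stratified folds column and a manifest. Byte-identical
    for identical (spec, seed)."""
    volumes, labels, folds, space = classification_dataset(spec)
    return _write_set(volumes, labels, folds, space, spec, out_dir)


def make_regression_volumes(spec: FixtureSpec, out_dir) -> dict:
    """Write a regression volume set (volumes, mask, scores, folds)."""
    volumes, scores, folds, space = regression_dataset(spec)
    return _write_set(volumes, scores, folds, space, spec, out_dir)
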