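"""Reading sample volumes/tables, labels, folds and masks; writing result maps.

The in-memory data model is deliberately small: a :class:`FeatureMatrix`
(samples x features) tied to either a :class:`VolumeSpace` (voxel geometry,
so per-feature results can be written back as NIfTI maps) or a
:class:`TabularSpace` (no geometry; connectivity vectors, behavioural or
genetic features).

Supported on-disk formats are NIfTI-1 (.nii/.nii.gz) for volumes, masks and
output maps, and header-free delimited text (whitespace/comma/tab) for
labels, folds and tabular feature matrices.  Surface (GIFTI), ANALYZE, .mat
and spreadsheet dialects are intentionally not supported; convert upstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "DataError",
    "GeometryError",
    "VolumeSpace",
    "TabularSpace",
    "FeatureMatrix",
    "LabelVector",
    "FoldAssignment",
    "load_samples",
    "load_table",
    "load_mask",
    "write_map",
]


class DataError(ValueError):
    """Invalid data content (NaN/Inf, bad labels, empty folds...)."""


class GeometryError(ValueError):
    """Volume shape/affine mismatch or missing geometry."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

_AFFINE_TOL = 1e-4


@dataclass(frozen=True)
class VolumeSpace:
    """Voxel-grid geometry mapping feature columns to voxel coordinates.

    Feature columns follow the canonical in-mask order: ascending linear
    voxel index with x varying fastest (Fortran order).  The order is a pure
    function of the mask, never of sample content.
    """

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray
    mask: np.ndarray  # boolean, shape == dims

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != tuple(self.dims):
            raise GeometryError(
                f"mask shape {mask.shape} does not match dims {self.dims}"
            )
        if not mask.any():
            raise DataError("empty mask: no in-mask voxels")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @property
    def n_features(self) -> int:
        return int(self.mask.sum())

    @property
    def mask_indices(self) -> np.ndarray:
        """In-mask voxel coordinates, one (x, y, z) row per feature column."""
        flat = np.flatnonzero(self.mask.reshape(-1, order="F"))
        return np.column_stack(np.unravel_index(flat, self.dims, order="F"))

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Pull the in-mask voxels of one volume in canonical column order."""
        if volume.shape != tuple(self.dims):
            raise GeometryError(
                f"volume shape {volume.shape} does not match dims {self.dims}"
            )
        flat = np.asarray(volume, dtype=float).reshape(-1, order="F")
        return flat[self.mask.reshape(-1, order="F")]

    def embed(self, values: Sequence[float], fill: float = 0.0) -> np.ndarray:
        """Scatter per-feature values back into a full volume array."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_features,):
            raise GeometryError(
                f"expected {self.n_features} values, got {values.shape}"
            )
        flat = np.full(int(np.prod(self.dims)), fill, dtype=float)
        flat[self.mask.reshape(-1, order="F")] = values
        return flat.reshape(self.dims, order="F")


@dataclass(frozen=True)
class TabularSpace:
    """Feature space of a delimited table: column count, no geometry."""

    n_features: int
    block_ranges: dict | None = None  # filled by fusion.concatenate_features


@dataclass
class FeatureMatrix:
    """Samples x features matrix plus the feature space it came from."""

    values: np.ndarray
    sample_ids: list[str]
    space: VolumeSpace | TabularSpace

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("feature matrix must be 2-D (samples x features)")
        if len(self.sample_ids) != self.values.shape[0]:
            raise DataError("sample_ids length must equal the number of rows")
        if self.values.shape[1] != self.space.n_features:
            raise GeometryError(
                f"matrix has {self.values.shape[1]} columns but the feature "
                f"space defines {self.space.n_features}"
            )
        if not np.isfinite(self.values).all():
            raise DataError("feature matrix contains NaN/Inf values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def restrict(self, columns: np.ndarray) -> "FeatureMatrix":
        """Sub-matrix on a column subset, as a tabular-space matrix."""
        cols = np.asarray(columns, dtype=int)
        return FeatureMatrix(
            self.values[:, cols], list(self.sample_ids), TabularSpace(len(cols))
        )


@dataclass(frozen=True)
class LabelVector:
    """Per-sample targets: two-class labels (canonically +1/-1) or scores."""

    kind: str  # "classification" | "regression"
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        if self.kind not in ("classification", "regression"):
            raise DataError(f"unknown label kind {self.kind!r}")
        if self.kind == "classification":
            values = canonicalize_labels(values)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


def canonicalize_labels(values: np.ndarray) -> np.ndarray:
    """Map two-class labels to the internal {+1, -1} convention.

    Accepts {1, -1} or the {1, 0} alias (0 -> -1).  More than two distinct
    classes is rejected: only two-way classification is supported.
    """
    values = np.asarray(values, dtype=float).ravel()
    classes = np.unique(values)
    if len(classes) > 2:
        raise DataError(
            f"{len(classes)} distinct classes found; only two-way "
            "classification is supported"
        )
    if len(classes) < 2:
        raise DataError("classification labels must contain two classes")
    if set(classes) == {0.0, 1.0}:
        return np.where(values == 0.0, -1.0, 1.0)
    if set(classes) == {-1.0, 1.0}:
        return values.astype(float)
    # any other two-class coding: larger value -> +1
    return np.where(values == classes[1], 1.0, -1.0)


@dataclass(frozen=True)
class FoldAssignment:
    """Per-sample fold index in 1..K; every fold non-empty, K >= 2."""

    fold_of_sample: np.ndarray
    K: int = field(default=0)

    def __post_init__(self) -> None:
        folds = np.asarray(self.fold_of_sample)
        if not np.all(folds == np.round(folds)):
            raise DataError("fold indices must be integers")
        folds = folds.astype(int)
        K = self.K or int(folds.max(initial=0))
        if K < 2:
            raise DataError("at least two folds are required")
        present = np.unique(folds)
        missing = sorted(set(range(1, K + 1)) - set(present.tolist()))
        if missing or present.min() < 1 or present.max() > K:
            raise DataError(
                f"fold vector must cover 1..{K} with no empty fold "
                f"(missing: {missing or 'out-of-range indices'})"
            )
        object.__setattr__(self, "fold_of_sample", folds)
        object.__setattr__(self, "K", K)

    def __len__(self) -> int:
        return len(self.fold_of_sample)

    def test_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_sample == k)

    def train_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_sample != k)


# --------------------------------------------------------------------------
# loading
# --------------------------------------------------------------------------

def _read_delimited(path: str | Path) -> np.ndarray:
    """Numeric header-free table; autodetects comma/tab/whitespace."""
    text = Path(path).read_text()
    delimiter = "," if "," in text else None
    try:
        arr = np.loadtxt(str(path), delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise DataError(f"non-numeric content in {path}: {exc}") from exc
    return arr


def load_mask(
    mask: str | Path | np.ndarray | VolumeSpace,
    reference: nib.Nifti1Image | None = None,
) -> VolumeSpace:
    """Build a :class:`VolumeSpace` from a mask image/array.

    Nonzero voxels are in-mask (files advertised as binary often hold
    near-1 floats after resampling).
    """
    if isinstance(mask, VolumeSpace):
        return mask
    if isinstance(mask, (str, Path)):
        img = nib.load(str(mask))
        data = np.asarray(img.dataobj, dtype=float)
        affine, zooms = img.affine, img.header.get_zooms()[:3]
    else:
        data = np.asarray(mask, dtype=float)
        if reference is not None:
            affine, zooms = reference.affine, reference.header.get_zooms()[:3]
        else:
            affine, zooms = np.eye(4), (1.0, 1.0, 1.0)
    if data.ndim != 3:
        raise GeometryError(f"mask must be 3-D, got shape {data.shape}")
    return VolumeSpace(
        dims=tuple(int(d) for d in data.shape),
        voxel_size=tuple(float(z) for z in zooms),
        affine=np.asarray(affine, dtype=float),
        mask=data != 0,
    )


def load_samples(
    paths: Sequence[str | Path],
    mask: str | Path | np.ndarray | VolumeSpace,
) -> FeatureMatrix:
    """Load one NIfTI volume per sample into a samples x voxels matrix.

    Rows follow the given file order; columns are the in-mask voxels in
    canonical order.  All volumes must share dims and affine (affine entries
    compared within 1e-4); NaN/Inf inside the mask is rejected naming the
    offending file.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise DataError("no sample files given")
    first = nib.load(str(paths[0]))
    space = load_mask(mask, reference=first)
    rows = []
    ref_affine = None
    for path in paths:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        if data.ndim != 3:
            raise GeometryError(f"{path.name}: expected a 3-D volume")
        if data.shape != tuple(space.dims):
            raise GeometryError(
                f"{path.name}: shape {data.shape} does not match mask dims "
                f"{space.dims}"
            )
        if ref_affine is None:
            ref_affine = img.affine
        elif np.max(np.abs(img.affine - ref_affine)) > _AFFINE_TOL:
            raise GeometryError(f"{path.name}: affine differs from first volume")
        row = space.extract(data)
        if not np.isfinite(row).all():
            raise DataError(f"{path.name}: NaN/Inf inside the mask")
        rows.append(row)
    return FeatureMatrix(np.vstack(rows), [p.name for p in paths], space)


def load_table(
    path: str | Path, expected: str
) -> LabelVector | FoldAssignment | FeatureMatrix:
    """Load a delimited numeric table as labels, folds, scores or features.

    ``expected`` is one of ``"labels"`` (two-class), ``"scores"``
    (regression targets), ``"folds"`` or ``"features"``.
    """
    arr = _read_delimited(path)
    if expected in ("labels", "scores", "folds") and arr.shape[1] != 1:
        raise DataError(
            f"{path}: expected a single column for {expected}, "
            f"got {arr.shape[1]} columns"
        )
    if expected == "labels":
        return LabelVector("classification", arr[:, 0])
    if expected == "scores":
        return LabelVector("regression", arr[:, 0])
    if expected == "folds":
        return FoldAssignment(arr[:, 0])
    if expected == "features":
        if not np.isfinite(arr).all():
            raise DataError(f"{path}: NaN/Inf in feature table")
        ids = [str(i) for i in range(arr.shape[0])]
        return FeatureMatrix(arr, ids, TabularSpace(arr.shape[1]))
    raise ValueError(f"unknown expected kind {expected!r}")


# --------------------------------------------------------------------------
# writing
# --------------------------------------------------------------------------

def write_map(
    values: Sequence[float], space: VolumeSpace | TabularSpace, path: str | Path
) -> Path:
    """Write a per-feature vector as a NIfTI map in the input geometry.

    In-mask voxels carry the values, out-of-mask voxels are zero; the header
    dims/affine are copied from the input geometry so maps overlay the
    source data.  Round-trips through :func:`load_samples` within 1e-6.
    """
    if not isinstance(space, VolumeSpace):
        raise GeometryError("no geometry to write: feature space is tabular")
    volume = space.embed(values)
    img = nib.Nifti1Image(volume.astype(np.float64), space.affine)
    img.header.set_zooms(space.voxel_size)
    path = Path(path)
    os.makedirs(path.parent, exist_ok=True)
    nib.save(img, str(path))
    return path


def write_table(array: np.ndarray, path: str | Path, header: str = "") -> Path:
    path = Path(path)
    os.makedirs(path.parent, exist_ok=True)
    np.savetxt(str(path), np.asarray(array), delimiter=",", header=header,
               comments="")
    return path
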