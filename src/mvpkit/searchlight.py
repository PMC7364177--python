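"""Searchlight information mapping: the CV pipeline inside a sphere per voxel.

For every in-mask voxel a sphere of a given radius (in voxel-lattice units
by default) collects the in-mask voxels around it; the full cross-validation
pipeline runs on those columns alone and the aggregate statistic (pooled
accuracy or prediction precision) is written at the center.  The result is a
statistic map plus a sphere-size map; permutation-based p-maps come from
:mod:`mvpkit.permstats`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import crossval
from .data_io import DataError, FeatureMatrix, GeometryError, VolumeSpace

__all__ = ["SphereIndex", "SearchlightResult", "build_spheres",
           "run_searchlight"]


@dataclass(frozen=True)
class SphereIndex:
    """Per-center membership: column indices of in-mask sphere voxels."""

    radius: float
    offsets: np.ndarray          # m x 3 integer offsets, ||d||^2 <= r^2
    per_center: tuple            # tuple of int arrays, one per feature column


def sphere_offsets(radius: float, voxel_size=None) -> np.ndarray:
    """All integer offsets within the closed ball of the given radius.

    With ``voxel_size`` given, the radius is in millimetres and offsets are
    measured in physical distance; otherwise in voxel-lattice units
    (Euclidean distance on the index grid).
    """
    if radius < 0:
        raise DataError("radius must be non-negative")
    scale = np.ones(3) if voxel_size is None else np.asarray(voxel_size, float)
    reach = [int(np.floor(radius / s)) for s in scale]
    axes = [np.arange(-r, r + 1) for r in reach]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d2 = ((grid * scale) ** 2).sum(axis=1)
    offsets = grid[d2 <= radius**2 + 1e-9]
    # deterministic order: ascending (x, y, z)
    order = np.lexsort((offsets[:, 2], offsets[:, 1], offsets[:, 0]))
    return offsets[order]


def build_spheres(space: VolumeSpace, radius: float,
                  units: str = "voxel") -> SphereIndex:
    """Index the in-mask sphere members around every in-mask center.

    Centers iterate in the canonical feature-column order; members are the
    in-mask voxels within the closed ball (out-of-volume and out-of-mask
    neighbours are dropped).
    """
    if units == "voxel":
        offsets = sphere_offsets(radius)
    elif units == "mm":
        offsets = sphere_offsets(radius, voxel_size=space.voxel_size)
    else:
        raise DataError(f"unknown radius units {units!r}")
    dims = np.asarray(space.dims)
    # map voxel coordinate -> feature column (-1 when out of mask)
    col_of = np.full(space.dims, -1, dtype=int, order="F")
    coords = space.mask_indices
    col_of[coords[:, 0], coords[:, 1], coords[:, 2]] = np.arange(len(coords))
    members = []
    for center in coords:
        pts = center + offsets
        ok = np.all((pts >= 0) & (pts < dims), axis=1)
        pts = pts[ok]
        cols = col_of[pts[:, 0], pts[:, 1], pts[:, 2]]
        members.append(np.sort(cols[cols >= 0]))
    return SphereIndex(radius, offsets, tuple(members))


@dataclass
class SearchlightResult:
    statistic_map: np.ndarray    # per-center pooled accuracy or r
    n_voxels_map: np.ndarray
    space: VolumeSpace
    radius: float


def run_searchlight(data: FeatureMatrix, labels, folds, radius: float,
                    pipeline: crossval.Pipeline, seed: int = 0,
                    units: str = "voxel",
                    sphere_index: SphereIndex | None = None,
                    eval_labels=None) -> SearchlightResult:
    """Map the CV statistic over every in-mask sphere.

    Each center's statistic depends only on its own sphere's columns; any
    model randomness is derived from (seed, center index), so output is
    independent of execution order.  Regression centers whose predictions
    are degenerate (zero variance, correlation undefined) carry NaN.
    """
    if not isinstance(data.space, VolumeSpace):
        raise GeometryError("searchlight requires geometry: feature space is "
                            "tabular")
    index = sphere_index or build_spheres(data.space, radius, units)
    n_centers = data.n_features
    stat = np.empty(n_centers)
    sizes = np.array([len(m) for m in index.per_center])
    for c in range(n_centers):
        sub = data.values[:, index.per_center[c]]
        center_seed = (int(seed) * 1_000_003 + c) % (2**31)
        try:
            result = crossval.run_cv(sub, labels, folds, pipeline,
                                     seed=center_seed, collect_weights=False,
                                     eval_labels=eval_labels)
            stat[c] = result.statistic
        except DataError:
            stat[c] = np.nan
    return SearchlightResult(stat, sizes, data.space, radius)
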