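"""Lesion-guided damaged-fiber modelling.

The method: superimpose a patient's binary lesion mask on normative
whole-brain tractograms and keep every streamline with at least one point
inside a lesion voxel.  From the selected streamlines two volumes are
built per database subject --

* a **count volume**: how many distinct damaged streamlines traverse each
  voxel (a streamline contributes at most 1 per voxel, so counts measure
  fibers rather than point density, which depends on the tracking step);
* a **distance volume**: mean arc-length distance from the lesion, measured
  along the streamlines, for every voxel traversed by at least one damaged
  streamline (NaN elsewhere).

Per-subject volumes are then averaged over the database to give the final
damage model for the patient, and models are mirrored along the first
(left-right) axis so the lesioned hemisphere is on a common side before
group analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grids import VolumeGrid, VolumeImage
from .io import Tractogram

__all__ = [
    "LesionMask",
    "DamageModel",
    "select_damaged_streamlines",
    "count_volume",
    "distance_volume",
    "subject_damage_volumes",
    "average_models",
    "standardize_hemisphere",
]


@dataclass
class LesionMask:
    """A binary lesion volume plus the hemisphere it sits in.

    ``side`` is the hemisphere of the lesion ('left'/'right') along the
    grid's first axis.  A mismatch between ``side`` and the sign of the
    lesion centroid's world x-coordinate is suspicious (but not fatal --
    midline lesions exist) and triggers a warning.
    """

    volume: VolumeImage
    side: str

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        data = np.asarray(self.volume.data)
        if not self.volume.is_binary():
            raise ValueError("lesion mask must be binary (0/1)")
        if not data.any():
            raise ValueError("lesion mask has no nonzero voxel")
        centroid_vox = np.argwhere(data).mean(axis=0)
        x_world = self.volume.grid.voxel_to_world(centroid_vox)[0]
        inferred = "right" if x_world > 0 else "left"
        if abs(x_world) > 1e-6 and inferred != self.side:
            warnings.warn(
                f"lesion centroid x={x_world:.1f} mm suggests side "
                f"{inferred!r}, not {self.side!r}",
                stacklevel=2,
            )

    @property
    def grid(self) -> VolumeGrid:
        return self.volume.grid


@dataclass
class DamageModel:
    """Averaged damaged-fiber model: count + distance volumes.

    ``count`` holds the mean number of damaged streamlines per voxel over
    the database; ``distance`` the mean along-streamline distance from the
    lesion (mm), NaN where no damaged streamline passes.
    """

    count: VolumeImage
    distance: VolumeImage
    n_subjects: int

    def __post_init__(self) -> None:
        self.count.grid.require_match(self.distance.grid, "count/distance volumes")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        cnt = np.asarray(self.count.data)
        dist = np.asarray(self.distance.data)
        if (cnt < 0).any():
            raise ValueError("count volume has negative values")
        defined = ~np.isnan(dist)
        if not np.array_equal(defined, cnt > 0):
            raise ValueError("distance must be defined exactly where count > 0")

    @property
    def grid(self) -> VolumeGrid:
        return self.count.grid


def _lesion_image(lesion: "LesionMask | VolumeImage") -> VolumeImage:
    """Accept a LesionMask or a bare binary VolumeImage (possibly empty)."""
    return lesion.volume if isinstance(lesion, LesionMask) else lesion


def _point_lesion_hits(points: np.ndarray, lesion) -> np.ndarray:
    """Boolean array: which polyline points fall in a lesion voxel."""
    vol = _lesion_image(lesion)
    grid = vol.grid
    idx = grid.world_to_voxel(points)
    inb = grid.in_bounds(idx)
    hits = np.zeros(len(points), dtype=bool)
    if inb.any():
        ii = idx[inb]
        hits[inb] = np.asarray(vol.data)[ii[:, 0], ii[:, 1], ii[:, 2]] > 0
    return hits


def select_damaged_streamlines(
    tractogram: Tractogram, lesion: "LesionMask | VolumeImage"
) -> np.ndarray:
    """Indices of streamlines with >= 1 point inside a lesion voxel.

    Point-in-voxel membership uses the nearest-voxel convention of
    :meth:`VolumeGrid.world_to_voxel`.  Order-stable (ascending indices).
    """
    tractogram.grid.require_match(_lesion_image(lesion).grid, "tractogram and lesion")
    if not tractogram.streamlines:
        return np.empty(0, dtype=np.int64)
    # one vectorized pass over all points, then reduce per streamline
    lengths = np.array([len(s) for s in tractogram.streamlines])
    allpts = np.concatenate(tractogram.streamlines, axis=0)
    hits = _point_lesion_hits(allpts, lesion)
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    any_hit = np.add.reduceat(hits, bounds[:-1]) > 0
    return np.flatnonzero(any_hit).astype(np.int64)


def _voxel_flat_indices(points: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    """Flat voxel index per point; -1 for out-of-bounds points."""
    idx = grid.world_to_voxel(points)
    inb = grid.in_bounds(idx)
    flat = np.full(len(points), -1, dtype=np.int64)
    if inb.any():
        flat[inb] = np.ravel_multi_index(
            (idx[inb, 0], idx[inb, 1], idx[inb, 2]), grid.dims
        )
    return flat


def count_volume(
    tractogram: Tractogram,
    selected: Sequence[int] | np.ndarray,
    grid: VolumeGrid | None = None,
) -> VolumeImage:
    """Number of distinct selected streamlines traversing each voxel."""
    grid = grid or tractogram.grid
    counts = np.zeros(grid.dims, dtype=np.float64).ravel()
    for i in np.asarray(selected, dtype=np.int64):
        flat = _voxel_flat_indices(tractogram.streamlines[i], grid)
        vox = np.unique(flat[flat >= 0])
        counts[vox] += 1.0
    return VolumeImage(grid, counts.reshape(grid.dims))


def _arc_lengths(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length (mm) along a polyline, starting at 0."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _per_point_lesion_distance(
    points: np.ndarray, lesion
) -> np.ndarray | None:
    """Arc-length distance from each point to its streamline's nearest
    lesion-interior point; None if the streamline misses the lesion."""
    hits = _point_lesion_hits(points, lesion)
    if not hits.any():
        return None
    arc = _arc_lengths(points)
    lesion_arcs = arc[hits]  # sorted, arc is monotone
    pos = np.searchsorted(lesion_arcs, arc)
    left = np.where(pos > 0, arc - lesion_arcs[np.maximum(pos - 1, 0)], np.inf)
    right = np.where(
        pos < len(lesion_arcs),
        lesion_arcs[np.minimum(pos, len(lesion_arcs) - 1)] - arc,
        np.inf,
    )
    return np.minimum(left, right)


def distance_volume(
    tractogram: Tractogram,
    selected: Sequence[int] | np.ndarray,
    lesion: "LesionMask | VolumeImage",
    grid: VolumeGrid | None = None,
) -> VolumeImage:
    """Mean along-streamline distance from the lesion per voxel (mm).

    For each selected streamline and each voxel it traverses, the
    contribution is the minimum cumulative arc length from any of that
    streamline's points in the voxel to the nearest of its lesion-interior
    points; the voxel value averages these contributions over streamlines.
    Voxels traversed by no selected streamline are NaN.
    """
    grid = grid or tractogram.grid
    grid.require_match(_lesion_image(lesion).grid, "tractogram and lesion")
    n = int(np.prod(grid.dims))
    dist_sum = np.zeros(n)
    traversals = np.zeros(n)
    for i in np.asarray(selected, dtype=np.int64):
        pts = tractogram.streamlines[i]
        d = _per_point_lesion_distance(pts, lesion)
        if d is None:
            raise ValueError(
                f"streamline {i} has no lesion-interior point; "
                "selection must precede distance_volume"
            )
        flat = _voxel_flat_indices(pts, grid)
        keep = flat >= 0
        flat, d = flat[keep], d[keep]
        order = np.argsort(flat, kind="stable")
        flat, d = flat[order], d[order]
        vox, start = np.unique(flat, return_index=True)
        per_vox = np.minimum.reduceat(d, start)
        dist_sum[vox] += per_vox
        traversals[vox] += 1.0
    with np.errstate(invalid="ignore"):
        mean = np.where(traversals > 0, dist_sum / np.maximum(traversals, 1), np.nan)
    return VolumeImage(grid, mean.reshape(grid.dims))


def subject_damage_volumes(
    tractogram: Tractogram, lesion: LesionMask
) -> tuple[VolumeImage, VolumeImage, int]:
    """Select + count + distance for one database subject.

    Returns (count, distance, n_selected).
    """
    sel = select_damaged_streamlines(tractogram, lesion)
    cnt = count_volume(tractogram, sel)
    dst = distance_volume(tractogram, sel, lesion)
    return cnt, dst, len(sel)


def average_models(
    models: Sequence[tuple[VolumeImage, VolumeImage]],
) -> DamageModel:
    """Average per-subject (count, distance) volumes over the database.

    Count is the plain arithmetic mean (zeros included).  Distance is the
    count-weighted mean over subjects with a defined distance at the voxel,
    so subjects contributing more damaged streamlines to a voxel weigh more;
    NaN where every subject's count is zero.
    """
    if not models:
        raise ValueError("average_models requires at least one model")
    grid = models[0][0].grid
    count_sum = np.zeros(grid.dims)
    wdist_sum = np.zeros(grid.dims)
    for cnt, dst in models:
        grid.require_match(cnt.grid, "damage models")
        c = np.asarray(cnt.data, dtype=float)
        d = np.asarray(dst.data, dtype=float)
        count_sum += c
        contrib = c > 0
        wdist_sum[contrib] += c[contrib] * d[contrib]
    n = len(models)
    mean_count = count_sum / n
    with np.errstate(invalid="ignore"):
        mean_dist = np.where(count_sum > 0, wdist_sum / np.maximum(count_sum, 1e-300), np.nan)
    return DamageModel(
        VolumeImage(grid, mean_count), VolumeImage(grid, mean_dist), n
    )


def _flip_x(data: np.ndarray) -> np.ndarray:
    return data[::-1, :, :].copy()


def standardize_hemisphere(model: DamageModel, deficit_side: str) -> DamageModel:
    """Mirror the model along the first (left-right) axis when needed.

    Patients with a *right*-sided motor deficit (left-hemisphere lesion)
    are flipped index-wise ``i -> Nx-1-i`` so the assumed lesioned
    hemisphere lies on the right for every subject; left-sided deficit
    models pass through unchanged.
    """
    if deficit_side not in ("left", "right"):
        raise ValueError(f"deficit_side must be 'left' or 'right', got {deficit_side!r}")
    if deficit_side == "left":
        return model
    return DamageModel(
        model.count.with_data(_flip_x(np.asarray(model.count.data))),
        model.distance.with_data(_flip_x(np.asarray(model.distance.data))),
        model.n_subjects,
    )
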