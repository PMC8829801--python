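"""Tract / lesion / distance-bin ROIs and ipsi-contra ratio tables.

The ipsilesional tract ROI is the thresholded damage model (strictly more
than ``count_threshold`` damaged fibers per voxel, default 3), minus the
primary-lesion voxels, minus voxels with FA below ``fa_floor`` (default
0.1, which drops CSF/grey matter where the tensor is unreliable).  The
contralesional reference ROI is its left-right mirror.  The tract ROI is
further split into distance bins (default five 10-mm shells of
along-streamline distance from the lesion), and per-ROI mean FA/MD/λ1/λ23
plus ipsi/contra ratios (rFA, rMD, rλ1, rλ23) are tabulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .damage import DamageModel, LesionMask
from .dti import DiffusionScalarSet
from .grids import VolumeImage

__all__ = [
    "RoiConfig",
    "RoiSet",
    "build_tract_roi",
    "mirror_mask",
    "bin_by_distance",
    "build_roi_set",
    "roi_means_and_ratios",
    "METRICS",
]

METRICS = ("fa", "md", "lambda1", "rd")
_METRIC_LABELS = {"fa": "FA", "md": "MD", "lambda1": "lambda1", "rd": "lambda23"}


@dataclass(frozen=True)
class RoiConfig:
    """Thresholds and distance edges for ROI construction.

    count_threshold : voxels must exceed this many damaged fibers
        (strict inequality) to enter the tract ROI.
    fa_floor : voxels with FA below this are excluded.
    distance_edges : bin edges in mm; bins are half-open [lo, hi).
    """

    count_threshold: float = 3.0
    fa_floor: float = 0.1
    distance_edges: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)

    def __post_init__(self) -> None:
        if self.count_threshold < 0:
            raise ValueError("count_threshold must be >= 0")
        edges = tuple(float(e) for e in self.distance_edges)
        if edges[0] != 0.0 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("distance_edges must start at 0 and increase strictly")
        object.__setattr__(self, "distance_edges", edges)

    @property
    def n_bins(self) -> int:
        return len(self.distance_edges) - 1

    def bin_labels(self) -> list[str]:
        e = self.distance_edges
        return [f"{e[i]:g}-{e[i+1]:g}mm" for i in range(self.n_bins)]


@dataclass
class RoiSet:
    """All ROIs for one patient: lesion, tract (ipsi/contra), distance bins."""

    lesion_roi: VolumeImage
    tract_ipsi: VolumeImage
    tract_contra: VolumeImage
    distance_bin_rois: list[VolumeImage] = field(default_factory=list)

    def __post_init__(self) -> None:
        les = np.asarray(self.lesion_roi.data) > 0
        ipsi = np.asarray(self.tract_ipsi.data) > 0
        if (les & ipsi).any():
            raise ValueError("tract ROI overlaps the primary lesion")
        union = np.zeros_like(ipsi)
        for b in self.distance_bin_rois:
            bb = np.asarray(b.data) > 0
            if (bb & union).any():
                raise ValueError("distance bins are not pairwise disjoint")
            if (bb & ~ipsi).any():
                raise ValueError("distance bin leaves the tract ROI")
            union |= bb


def build_tract_roi(
    model: DamageModel,
    lesion: LesionMask,
    fa_map: VolumeImage,
    config: RoiConfig = RoiConfig(),
) -> VolumeImage:
    """Binary ipsilesional tract ROI.

    voxel in ROI  <=>  count > threshold  AND  not lesion  AND  FA >= floor.
    """
    model.grid.require_match(lesion.grid, "damage model and lesion")
    model.grid.require_match(fa_map.grid, "damage model and FA map")
    cnt = np.asarray(model.count.data)
    les = np.asarray(lesion.volume.data) > 0
    fa = np.asarray(fa_map.data)
    roi = (cnt > config.count_threshold) & ~les & (fa >= config.fa_floor)
    if not roi.any():
        warnings.warn("tract ROI is empty under the given thresholds", stacklevel=2)
    return VolumeImage(model.grid, roi.astype(np.uint8))


def mirror_mask(mask: VolumeImage) -> VolumeImage:
    """Flip a volume along the first (left-right) axis: i -> Nx-1-i."""
    return mask.with_data(np.asarray(mask.data)[::-1, :, :].copy())


def bin_by_distance(
    tract_roi: VolumeImage,
    distance: VolumeImage,
    config: RoiConfig = RoiConfig(),
) -> list[VolumeImage]:
    """Split the tract ROI into half-open distance shells [lo, hi).

    Voxels beyond the last edge belong to no bin; tract voxels with an
    undefined (NaN) distance are likewise unassigned (count is logged).
    """
    tract_roi.grid.require_match(distance.grid, "tract ROI and distance volume")
    roi = np.asarray(tract_roi.data) > 0
    d = np.asarray(distance.data, dtype=float)
    undefined = roi & np.isnan(d)
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} tract-ROI voxels have undefined distance "
            "and fall in no bin",
            stacklevel=2,
        )
    bins = []
    edges = config.distance_edges
    for lo, hi in zip(edges, edges[1:]):
        with np.errstate(invalid="ignore"):
            member = roi & ~np.isnan(d) & (d >= lo) & (d < hi)
        bins.append(tract_roi.with_data(member.astype(np.uint8)))
    return bins


def build_roi_set(
    model: DamageModel,
    lesion: LesionMask,
    fa_map: VolumeImage,
    config: RoiConfig = RoiConfig(),
) -> RoiSet:
    """Assemble lesion ROI, tract ROI + mirror, and distance bins."""
    tract = build_tract_roi(model, lesion, fa_map, config)
    bins = bin_by_distance(tract, model.distance, config)
    return RoiSet(
        lesion_roi=lesion.volume.with_data(
            (np.asarray(lesion.volume.data) > 0).astype(np.uint8)
        ),
        tract_ipsi=tract,
        tract_contra=mirror_mask(tract),
        distance_bin_rois=bins,
    )


def _mean_in(data: np.ndarray, mask: np.ndarray) -> float:
    return float(np.mean(data[mask])) if mask.any() else float("nan")


def roi_means_and_ratios(
    scalars: DiffusionScalarSet,
    rois: RoiSet,
    subject: str = "",
    timepoint: str = "",
) -> pd.DataFrame:
    """Tidy table of per-ROI means and ipsi/contra ratios.

    One row per (roi, metric): ipsilesional mean (over the ROI), the
    contralesional mean (over the mirrored ROI), and their ratio.  ROIs:
    the primary lesion, the full tract, and each distance bin.  An empty
    ROI yields NaN means; a zero contralesional mean yields a NaN ratio
    with a warning.
    """
    labeled: list[tuple[str, np.ndarray]] = [
        ("lesion", np.asarray(rois.lesion_roi.data) > 0),
        ("tract", np.asarray(rois.tract_ipsi.data) > 0),
    ]
    edges_labels = None
    if rois.distance_bin_rois:
        n = len(rois.distance_bin_rois)
        edges_labels = [f"bin{i+1}" for i in range(n)]
        for lab, b in zip(edges_labels, rois.distance_bin_rois):
            labeled.append((lab, np.asarray(b.data) > 0))

    rows = []
    for roi_label, ipsi_mask in labeled:
        contra_mask = ipsi_mask[::-1, :, :]
        for metric in METRICS:
            data = scalars.metric(metric)
            ipsi = _mean_in(data, ipsi_mask)
            contra = _mean_in(data, contra_mask)
            if contra == 0:
                warnings.warn(
                    f"contralesional mean of {metric} is 0 in {roi_label}; "
                    "ratio undefined",
                    stacklevel=2,
                )
                ratio = float("nan")
            else:
                ratio = ipsi / contra
            rows.append(
                {
                    "subject": subject,
                    "timepoint": timepoint,
                    "roi": roi_label,
                    "metric": _METRIC_LABELS[metric],
                    "n_voxels": int(ipsi_mask.sum()),
                    "ipsi_mean": ipsi,
                    "contra_mean": contra,
                    "ratio": ratio,
                }
            )
    return pd.DataFrame(rows)
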