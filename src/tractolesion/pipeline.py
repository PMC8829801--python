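"""End-to-end per-patient analysis: damage model -> ROIs -> metric table.

The in-memory entry points (:func:`build_damage_model`,
:func:`analyze_patient`) run the full sequence -- streamline selection,
count/distance volumes per database subject, database averaging,
hemisphere standardization, ROI construction, distance bins, per-ROI
means and ipsi/contra ratios for each timepoint.  :func:`run_patient_analysis`
wraps them with file IO driven by an :class:`AnalysisConfig` (YAML/JSON
round-trippable), writing every intermediate volume plus a checksum
manifest so a rerun with the same config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .damage import (
    DamageModel,
    LesionMask,
    average_models,
    standardize_hemisphere,
    subject_damage_volumes,
)
from .dti import DiffusionScalarSet, scalar_set_from_eigenvalues
from .grids import VolumeImage
from .io import (
    DISTANCE_SENTINEL,
    Tractogram,
    read_mask,
    read_tractogram,
    read_volume,
    write_volume,
)
from .roi import RoiConfig, build_roi_set, roi_means_and_ratios

logger = logging.getLogger("tractolesion")

__all__ = [
    "AnalysisConfig",
    "PipelineError",
    "build_damage_model",
    "analyze_patient",
    "run_patient_analysis",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Everything one patient analysis needs, serializable to YAML/JSON."""

    tractogram_paths: list[str]
    lesion_path: str
    # timepoint -> metric name -> path; metrics: lambda1, lambda2, lambda3
    eigenvalue_paths: dict
    deficit_side: str = "left"
    lesion_side: str = "right"
    count_threshold: float = 3.0
    fa_floor: float = 0.1
    distance_edges: list = field(default_factory=lambda: [0, 10, 20, 30, 40, 50])
    roi_fa_timepoint: str = ""  # "" = first timepoint listed
    output_dir: str = "tractolesion_out"
    seed: int = 0

    def roi_config(self) -> RoiConfig:
        return RoiConfig(
            count_threshold=self.count_threshold,
            fa_floor=self.fa_floor,
            distance_edges=tuple(float(e) for e in self.distance_edges),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def build_damage_model(
    tractograms: list[Tractogram], lesion: LesionMask
) -> tuple[DamageModel, list[int]]:
    """Per-subject damage volumes averaged over the database.

    Returns the averaged model and the number of selected streamlines per
    database subject (logged for provenance).
    """
    if not tractograms:
        raise ValueError("empty tractogram database")
    models, n_selected = [], []
    for i, t in enumerate(tractograms):
        cnt, dst, n_sel = subject_damage_volumes(t, lesion)
        models.append((cnt, dst))
        n_selected.append(n_sel)
        logger.info("database subject %d: %d damaged streamlines", i, n_sel)
    return average_models(models), n_selected


def analyze_patient(
    model: DamageModel,
    lesion: LesionMask,
    scalars_by_timepoint: dict[str, DiffusionScalarSet],
    config: RoiConfig = RoiConfig(),
    roi_fa_timepoint: str | None = None,
    subject: str = "",
) -> pd.DataFrame:
    """ROI construction + per-timepoint metric table for one patient.

    The tract ROI is built once, from the FA map of ``roi_fa_timepoint``
    (default: first timepoint), and held fixed across timepoints so the
    longitudinal comparison uses identical voxels.
    """
    timepoints = list(scalars_by_timepoint)
    if not timepoints:
        raise ValueError("no timepoints supplied")
    fa_tp = roi_fa_timepoint or timepoints[0]
    fa_map = VolumeImage(
        scalars_by_timepoint[fa_tp].grid, scalars_by_timepoint[fa_tp].fa
    )
    rois = build_roi_set(model, lesion, fa_map, config)
    tables = [
        roi_means_and_ratios(scalars_by_timepoint[tp], rois, subject=subject, timepoint=tp)
        for tp in timepoints
    ]
    return pd.concat(tables, ignore_index=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_patient_analysis(config: AnalysisConfig) -> pd.DataFrame:
    """File-driven per-patient analysis with on-disk artifacts.

    Writes the averaged count/distance volumes, the ROI metric table
    (TSV), and a JSON manifest with SHA-256 checksums of every output.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    stage = "load-lesion"
    try:
        lesion = LesionMask(read_mask(config.lesion_path), config.lesion_side)
    except Exception as exc:
        raise PipelineError(stage, f"{config.lesion_path}: {exc}") from exc

    stage = "load-tractograms"
    tractograms = []
    for p in config.tractogram_paths:
        try:
            tractograms.append(read_tractogram(p, grid=lesion.grid))
        except Exception as exc:
            raise PipelineError(stage, f"{p}: {exc}") from exc
    if not tractograms:
        raise PipelineError(stage, "no tractograms listed")

    stage = "damage-model"
    try:
        model, n_selected = build_damage_model(tractograms, lesion)
        model = standardize_hemisphere(model, config.deficit_side)
        std_lesion = lesion
        if config.deficit_side == "right":
            flipped = np.asarray(lesion.volume.data)[::-1, :, :].copy()
            std_lesion = LesionMask(lesion.volume.with_data(flipped), "right")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "load-scalars"
    scalars: dict[str, DiffusionScalarSet] = {}
    try:
        for tp, paths in config.eigenvalue_paths.items():
            l1 = read_volume(paths["lambda1"])
            l2 = read_volume(paths["lambda2"])
            l3 = read_volume(paths["lambda3"])
            lesion.grid.require_match(l1.grid, "lesion and eigenvalue maps")
            scalars[tp] = scalar_set_from_eigenvalues(
                l1.grid, np.asarray(l1.data, float), np.asarray(l2.data, float),
                np.asarray(l3.data, float),
            )
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "roi-analysis"
    try:
        table = analyze_patient(
            model, std_lesion, scalars, config.roi_config(),
            roi_fa_timepoint=config.roi_fa_timepoint or None,
        )
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "write-outputs"
    # uncompressed NIfTI so reruns are bitwise-identical (gzip embeds mtime)
    count_path = out / "damage_count.nii"
    dist_path = out / "damage_distance.nii"
    table_path = out / "roi_metrics.tsv"
    write_volume(model.count, count_path, "mean damaged-streamline count")
    write_volume(
        model.distance, dist_path, "mean along-streamline distance from lesion (mm).",
        nan_fill=DISTANCE_SENTINEL,
    )
    table.to_csv(table_path, sep="\t", index=False)

    manifest = {
        "config": asdict(config),
        "n_database_subjects": model.n_subjects,
        "selected_streamlines_per_subject": n_selected,
        "wall_time_s": round(time.time() - t0, 3),
        "outputs": {p.name: _sha256(p) for p in (count_path, dist_path, table_path)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("analysis complete in %.1f s", time.time() - t0)
    return table
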