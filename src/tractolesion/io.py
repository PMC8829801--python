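"""Reading and writing the neuroimaging formats the pipeline touches.

Tractograms (TCK/TRK) and volumes (NIfTI-1) go through nibabel.  On-disk
spatial conventions differ between formats -- TRK stores voxel-scaled
coordinates, TCK stores RAS mm -- but everything in memory is world mm:
nibabel's lazy tractogram machinery applies the header transform at load
time and we always request RAS mm ("rasmm") coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import VolumeGrid, VolumeImage

__all__ = [
    "Tractogram",
    "TractogramFormatError",
    "read_tractogram",
    "write_tractogram",
    "read_volume",
    "write_volume",
    "read_mask",
]

#: on-disk sentinel for "distance undefined here" (NaN in memory)
DISTANCE_SENTINEL = -1.0


class TractogramFormatError(ValueError):
    """A tractogram file does not conform to its declared format."""


@dataclass
class Tractogram:
    """A set of streamlines (world-mm polylines) with a reference grid.

    ``streamlines`` is a list of (n_i, 3) float arrays, each with >= 2
    points.  The grid defines the voxel lattice used for lesion membership
    and for rasterizing count/distance volumes.
    """

    streamlines: list[np.ndarray]
    grid: VolumeGrid

    def __post_init__(self) -> None:
        cleaned = []
        for i, s in enumerate(self.streamlines):
            arr = np.asarray(s, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"streamline {i} is not an (n, 3) array")
            if len(arr) < 2:
                raise ValueError(f"streamline {i} has fewer than 2 points")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"streamline {i} contains non-finite coordinates")
            cleaned.append(arr)
        self.streamlines = cleaned

    def __len__(self) -> int:
        return len(self.streamlines)


def _grid_from_nib(img_shape, affine) -> VolumeGrid:
    return VolumeGrid(tuple(int(d) for d in img_shape[:3]), np.asarray(affine, float))


def _trk_header(grid: VolumeGrid) -> dict:
    return {
        nib.streamlines.Field.VOXEL_TO_RASMM: grid.affine.astype(np.float32),
        nib.streamlines.Field.VOXEL_SIZES: grid.voxel_sizes.astype(np.float32),
        nib.streamlines.Field.DIMENSIONS: np.asarray(grid.dims, np.int16),
        nib.streamlines.Field.VOXEL_ORDER: b"RAS",
    }


def read_tractogram(path: str | Path, grid: VolumeGrid | None = None) -> Tractogram:
    """Load a TCK or TRK file as world-mm streamlines.

    TRK voxel-order / voxel-size quirks are normalized by nibabel using the
    file header; the returned coordinates are RAS mm regardless of format.

    Parameters
    ----------
    path : path to a ``.tck`` or ``.trk`` file (format from extension).
    grid : reference grid.  Required for TCK (the format carries no grid);
        for TRK it defaults to the grid recorded in the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tfile = nib.streamlines.load(str(path), lazy_load=False)
    except Exception as exc:  # nibabel raises assorted header errors
        raise TractogramFormatError(f"cannot parse {path.name}: {exc}") from exc

    if grid is None:
        hdr = tfile.header
        # only TRK headers carry a full reference grid; TCK does not
        if isinstance(tfile, nib.streamlines.TrkFile):
            grid = _grid_from_nib(
                hdr[nib.streamlines.Field.DIMENSIONS],
                hdr[nib.streamlines.Field.VOXEL_TO_RASMM],
            )
        else:
            raise ValueError(
                f"{path.name} carries no reference grid; pass `grid` explicitly"
            )
    streamlines = [np.asarray(s, dtype=float) for s in tfile.streamlines]
    if not streamlines:
        warnings.warn(f"{path.name} contains zero streamlines", stacklevel=2)
        return Tractogram([], grid)
    return Tractogram(streamlines, grid)


def write_tractogram(tractogram: Tractogram, path: str | Path) -> None:
    """Write streamlines to TCK or TRK (format chosen by extension)."""
    path = Path(path)
    sft = nib.streamlines.Tractogram(
        tractogram.streamlines, affine_to_rasmm=np.eye(4)
    )
    suffix = path.suffix.lower()
    if suffix == ".trk":
        nib.streamlines.save(sft, str(path), header=_trk_header(tractogram.grid))
    elif suffix == ".tck":
        nib.streamlines.save(sft, str(path))
    else:
        raise ValueError(f"unsupported tractogram format: {suffix}")


def read_volume(path: str | Path) -> VolumeImage:
    """Load a 3D NIfTI volume, preserving data and affine."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{Path(path).name} is {data.ndim}D; expected a 3D volume")
    return VolumeImage(_grid_from_nib(data.shape, img.affine), data)


def write_volume(
    volume: VolumeImage,
    path: str | Path,
    description: str = "",
    nan_fill: float | None = None,
) -> None:
    """Write a volume as NIfTI-1.

    ``nan_fill`` replaces NaN (in-memory undefined sentinel) on disk, e.g.
    -1 for distance volumes; the substitution is noted in the header
    description field.
    """
    data = np.asarray(volume.data)
    if nan_fill is not None and np.issubdtype(data.dtype, np.floating):
        data = np.where(np.isnan(data), nan_fill, data)
        description = (description + f" NaN stored as {nan_fill:g}.").strip()
    img = nib.Nifti1Image(data, volume.grid.affine)
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def read_mask(path: str | Path) -> VolumeImage:
    """Load a binary mask; any nonzero voxel becomes 1."""
    vol = read_volume(path)
    return vol.with_data((np.asarray(vol.data) != 0).astype(np.uint8))
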