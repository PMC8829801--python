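"""Voxel grids and volumes: the coordinate contract for the whole pipeline.

Every spatial object in an analysis lives on one shared :class:`VolumeGrid`
(dims + voxel->world affine).  Streamline coordinates are always world mm;
a world point belongs to the voxel whose center is nearest along each axis
(``floor(affine^-1 @ p + 0.5)``, 0-based indices).  Volumes on mismatched
grids are a hard error -- spatial normalization happens upstream, not here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGrid", "VolumeImage", "GridMismatchError"]

#: tolerance for declaring two affines "the same grid"
AFFINE_ATOL = 1e-4


class GridMismatchError(ValueError):
    """Raised when volumes/tractograms from different grids are combined."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D voxel lattice with an affine voxel-index -> world-mm mapping.

    Parameters
    ----------
    dims : tuple of int
        Number of voxels along each axis; all strictly positive.
    affine : (4, 4) ndarray
        Invertible homogeneous transform taking 0-based voxel indices to
        world coordinates in mm.
    """

    dims: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError(f"dims must be three positive integers, got {self.dims}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got shape {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "dims", dims)
        affine = affine.copy()
        affine.flags.writeable = False
        object.__setattr__(self, "affine", affine)

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Edge length of a voxel along each axis (mm)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_diagonal(self) -> float:
        """Length of the voxel body diagonal (mm)."""
        return float(np.linalg.norm(self.voxel_sizes))

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm coordinates."""
        idx = np.asarray(indices, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel_continuous(self, points: np.ndarray) -> np.ndarray:
        """Map (..., 3) world points to fractional voxel coordinates."""
        pts = np.asarray(points, dtype=float)
        inv = self.inverse_affine
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world points to the nearest voxel index (may be out of bounds).

        Nearest-voxel convention: ``i = floor(affine^-1 @ p + 0.5)``.
        """
        return np.floor(self.world_to_voxel_continuous(points) + 0.5).astype(np.int64)

    def in_bounds(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices)
        return np.all((idx >= 0) & (idx < np.array(self.dims)), axis=-1)

    def matches(self, other: "VolumeGrid", atol: float = AFFINE_ATOL) -> bool:
        return self.dims == other.dims and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_match(self, other: "VolumeGrid", what: str = "volumes") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"{what} are defined on different grids "
                f"(dims {self.dims} vs {other.dims}); reslicing is not performed"
            )


@dataclass
class VolumeImage:
    """A scalar or binary 3D array bound to a :class:`VolumeGrid`."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got {self.data.ndim}D")
        if self.data.shape != self.grid.dims:
            raise ValueError(
                f"data shape {self.data.shape} does not match grid dims {self.grid.dims}"
            )

    def is_binary(self) -> bool:
        return bool(np.isin(np.unique(self.data), (0, 1)).all())

    def with_data(self, data: np.ndarray) -> "VolumeImage":
        return VolumeImage(self.grid, data)

    def copy(self) -> "VolumeImage":
        return VolumeImage(self.grid, self.data.copy())
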