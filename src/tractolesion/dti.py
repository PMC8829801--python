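"""Diffusion-tensor fitting and scalar maps (FA, MD, AD=λ1, RD=λ23).

The tensor D is fitted voxel-wise by ordinary least squares on
log(S/S0) = -b gᵀDg (log-linear fit, no weighting, no positivity
constraint); eigenvalues are extracted with a batched symmetric
eigendecomposition and the scalars follow the standard definitions

    MD = (λ1+λ2+λ3)/3
    RD = (λ2+λ3)/2          (written λ23 throughout)
    FA = sqrt(1/2 * [(λ1-λ2)² + (λ1-λ3)² + (λ2-λ3)²] / (λ1²+λ2²+λ3²))

with FA := 0 at all-zero voxels.  Negative eigenvalues from noisy fits are
kept as-is; downstream ROI construction excludes low-FA voxels instead of
clipping here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grids import VolumeGrid, VolumeImage

__all__ = [
    "TensorVolume",
    "DiffusionScalarSet",
    "GradientTable",
    "fit_tensor_lls",
    "eigen_decompose",
    "compute_scalars",
    "scalar_set_from_eigenvalues",
    "predict_signal",
]

# row order of the 6 unique tensor components everywhere in this module
_COMP = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


@dataclass
class GradientTable:
    """Diffusion gradient scheme: unit directions and b-values (s/mm²)."""

    bvecs: np.ndarray  # (n, 3), zero rows for b=0 volumes
    bvals: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise ValueError("bvecs must be (n, 3)")
        if len(self.bvals) != len(self.bvecs):
            raise ValueError("bvals and bvecs disagree in length")
        norms = np.linalg.norm(self.bvecs, axis=1)
        dwi = self.bvals > 0
        if dwi.any():
            self.bvecs = self.bvecs.copy()
            self.bvecs[dwi] /= norms[dwi, None]

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvals == 0))

    @classmethod
    def from_fsl(cls, bvecs_path: str | Path, bvals_path: str | Path) -> "GradientTable":
        """Read the FSL dialect: bvecs is 3 rows x n cols, bvals one row."""
        bvecs = np.loadtxt(bvecs_path)
        bvals = np.loadtxt(bvals_path)
        if bvecs.shape[0] == 3 and bvecs.shape[0] != bvecs.shape[1]:
            bvecs = bvecs.T
        return cls(bvecs, np.atleast_1d(bvals))

    def design_matrix(self) -> np.ndarray:
        """(n, 7) design: [-b gx², -b gy², -b gz², -2b gxgy, -2b gxgz, -2b gygz, 1]."""
        g, b = self.bvecs, self.bvals
        return np.column_stack(
            [
                -b * g[:, 0] ** 2,
                -b * g[:, 1] ** 2,
                -b * g[:, 2] ** 2,
                -2 * b * g[:, 0] * g[:, 1],
                -2 * b * g[:, 0] * g[:, 2],
                -2 * b * g[:, 1] * g[:, 2],
                np.ones(len(b)),
            ]
        )


@dataclass
class TensorVolume:
    """Six unique tensor components per voxel (mm²/s) plus a validity mask."""

    grid: VolumeGrid
    components: np.ndarray  # (X, Y, Z, 6) in _COMP order
    mask: np.ndarray  # (X, Y, Z) bool

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.components.shape != self.grid.dims + (6,):
            raise ValueError("components must have shape dims + (6,)")
        if self.mask.shape != self.grid.dims:
            raise ValueError("mask shape must match grid dims")

    def as_matrices(self) -> np.ndarray:
        """(X, Y, Z, 3, 3) symmetric matrices."""
        c = self.components
        m = np.zeros(self.grid.dims + (3, 3))
        m[..., 0, 0] = c[..., 0]
        m[..., 1, 1] = c[..., 1]
        m[..., 2, 2] = c[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = c[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = c[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = c[..., 5]
        return m


@dataclass
class DiffusionScalarSet:
    """Eigenvalue maps (descending) and derived scalars for one scan."""

    grid: VolumeGrid
    lambda1: np.ndarray
    lambda2: np.ndarray
    lambda3: np.ndarray
    fa: np.ndarray
    md: np.ndarray
    rd: np.ndarray

    def metric(self, name: str) -> np.ndarray:
        key = name.lower()
        aliases = {"l1": "lambda1", "ad": "lambda1", "l23": "rd", "lambda23": "rd"}
        return getattr(self, aliases.get(key, key))

    def as_images(self) -> dict[str, VolumeImage]:
        return {
            k: VolumeImage(self.grid, getattr(self, k))
            for k in ("lambda1", "lambda2", "lambda3", "fa", "md", "rd")
        }


def predict_signal(
    components: np.ndarray, gradients: GradientTable, s0: float | np.ndarray = 1.0
) -> np.ndarray:
    """Forward model S = S0 exp(-b gᵀDg) for (..., 6) tensor components."""
    X = gradients.design_matrix()[:, :6]  # (n, 6); columns are -b g_i g_j terms
    logatt = np.asarray(components) @ X.T
    return np.asarray(s0)[..., None] * np.exp(logatt) if np.ndim(s0) else s0 * np.exp(logatt)


def fit_tensor_lls(
    dwi: np.ndarray,
    gradients: GradientTable,
    grid: VolumeGrid,
    mask: np.ndarray | None = None,
) -> TensorVolume:
    """Ordinary log-linear least-squares tensor fit.

    Parameters
    ----------
    dwi : (X, Y, Z, n) signal array, one volume per gradient table row.
    gradients : acquisition scheme; needs >= 6 non-collinear directions and
        >= 1 b=0 volume (7 independent columns overall).
    mask : voxels to fit; defaults to all.  Voxels with any non-positive
        signal are dropped from the output mask.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4:
        raise ValueError("dwi must be 4D (x, y, z, volumes)")
    if dwi.shape[:3] != grid.dims:
        raise ValueError("dwi spatial shape does not match grid")
    if dwi.shape[3] != len(gradients.bvals):
        raise ValueError("number of volumes does not match gradient table")
    if dwi.shape[3] < 7 or gradients.n_b0 < 1 or np.sum(gradients.bvals > 0) < 6:
        raise ValueError(
            "insufficient data: need >= 6 diffusion-weighted volumes plus a b=0"
        )
    X = gradients.design_matrix()
    rank = np.linalg.matrix_rank(X)
    if rank < 7:
        raise ValueError(
            f"singular design: rank {rank} < 7 (collinear gradient directions)"
        )

    if mask is None:
        mask = np.ones(grid.dims, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    signals = dwi[mask]  # (v, n)
    valid = np.all(signals > 0, axis=1)
    coeffs = np.zeros((signals.shape[0], 7))
    if valid.any():
        y = np.log(signals[valid])
        sol, *_ = np.linalg.lstsq(X, y.T, rcond=None)
        coeffs[valid] = sol.T

    components = np.zeros(grid.dims + (6,))
    components[mask] = coeffs[:, :6]
    out_mask = np.zeros(grid.dims, dtype=bool)
    out_mask[mask] = valid
    return TensorVolume(grid, components, out_mask)


def eigen_decompose(tensor: TensorVolume) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-wise eigenvalues of the tensor, sorted descending.

    Returns (λ1, λ2, λ3) maps; voxels outside the mask (or with non-finite
    components) are zero.
    """
    mats = tensor.as_matrices()
    finite = np.all(np.isfinite(tensor.components), axis=-1)
    ok = tensor.mask & finite
    lams = np.zeros(tensor.grid.dims + (3,))
    if ok.any():
        w = np.linalg.eigvalsh(mats[ok])  # ascending
        lams[ok] = w[:, ::-1]
    return lams[..., 0], lams[..., 1], lams[..., 2]


def compute_scalars(
    lambda1: np.ndarray, lambda2: np.ndarray, lambda3: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(FA, MD, RD) from sorted eigenvalue maps; FA=0 where all λ are 0."""
    l1 = np.asarray(lambda1, dtype=float)
    l2 = np.asarray(lambda2, dtype=float)
    l3 = np.asarray(lambda3, dtype=float)
    md = (l1 + l2 + l3) / 3.0
    rd = (l2 + l3) / 2.0
    num = (l1 - l2) ** 2 + (l1 - l3) ** 2 + (l2 - l3) ** 2
    den = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    return fa, md, rd


def scalar_set_from_eigenvalues(
    grid: VolumeGrid,
    lambda1: np.ndarray,
    lambda2: np.ndarray,
    lambda3: np.ndarray,
) -> DiffusionScalarSet:
    """Bundle eigenvalue maps with their derived scalars."""
    fa, md, rd = compute_scalars(lambda1, lambda2, lambda3)
    return DiffusionScalarSet(
        grid,
        np.asarray(lambda1, float),
        np.asarray(lambda2, float),
        np.asarray(lambda3, float),
        fa,
        md,
        rd,
    )
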