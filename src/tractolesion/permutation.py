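"""One-sample sign-flip permutation inference with max-statistic FWE control.

Given per-subject images, the voxelwise one-sample t (optionally a pseudo-t
with Gaussian-smoothed variance) is compared against its permutation null:
each permutation multiplies every subject's image by +-1 and recomputes the
statistic, and the image-wide maximum over the mask forms the null
distribution.  The FWE-corrected p at a voxel is the fraction of
permutations whose maximum reaches that voxel's observed statistic.  When
2^n <= n_perm all sign assignments are enumerated exactly (for n=11
subjects, 2048 permutations is exactly exhaustive); otherwise the identity
assignment plus n_perm-1 random flips are used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import VolumeImage

__all__ = ["PermutationResult", "sign_flip_one_sample"]


@dataclass
class PermutationResult:
    pseudo_t: VolumeImage
    fwe_p: VolumeImage
    null_max_distribution: np.ndarray
    n_permutations_used: int
    exhaustive: bool


def _fwhm_to_sigma_vox(fwhm_mm: float, voxel_sizes: np.ndarray) -> np.ndarray:
    return (fwhm_mm / np.sqrt(8.0 * np.log(2.0))) / voxel_sizes


def _statistics(
    data: np.ndarray,  # (n_subj, n_vox)
    signs: np.ndarray,  # (n_perm, n_subj)
    smoother=None,
) -> np.ndarray:
    """t (or pseudo-t) per permutation and voxel, fully vectorized.

    Sign flipping leaves sum(x^2) unchanged, so the sample variance under
    signs s is (ssq - n*mean^2)/(n-1) with mean = (s @ x)/n.
    """
    n = data.shape[0]
    ssq = np.sum(data**2, axis=0)  # (n_vox,)
    mean = signs @ data / n  # (n_perm, n_vox)
    var = np.maximum(ssq[None, :] - n * mean**2, 0.0) / (n - 1)
    if smoother is not None:
        var = smoother(var)
    se = np.sqrt(var / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / se
    t[~np.isfinite(t)] = 0.0
    return t


def sign_flip_one_sample(
    images: list[VolumeImage] | np.ndarray,
    mask: VolumeImage | np.ndarray,
    n_perm: int = 2048,
    variance_smoothing_fwhm: float | None = None,
    seed: int | None = 0,
) -> PermutationResult:
    """One-sample sign-flip permutation test over a voxel mask.

    Parameters
    ----------
    images : per-subject volumes sharing one grid (>= 2 subjects).
    mask : analysis mask; statistics and the max-statistic are restricted
        to its nonzero voxels.
    n_perm : permutations requested (>= 2).  If 2^n_subjects <= n_perm the
        full sign assignment set is enumerated (deterministic, seed
        ignored) and exactly 2^n_subjects permutations are used.
    variance_smoothing_fwhm : optional Gaussian FWHM (mm) applied to the
        voxelwise variance image before forming the statistic (pseudo-t);
        None gives the classical one-sample t.
    seed : RNG seed for the non-exhaustive branch.

    Notes
    -----
    The identity assignment is always included, so the smallest attainable
    FWE p is 1/n_permutations_used.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    if isinstance(mask, VolumeImage):
        grid = mask.grid
        mask_arr = np.asarray(mask.data) > 0
    else:
        grid = None
        mask_arr = np.asarray(mask) > 0
    if not mask_arr.any():
        raise ValueError("mask is empty")

    vols = []
    for img in images:
        if isinstance(img, VolumeImage):
            if grid is None:
                grid = img.grid
            else:
                grid.require_match(img.grid, "subject images and mask")
            vols.append(np.asarray(img.data, dtype=float))
        else:
            vols.append(np.asarray(img, dtype=float))
    if len(vols) < 2:
        raise ValueError("need >= 2 subjects")
    stack = np.stack(vols)  # (n, X, Y, Z)
    n = stack.shape[0]
    data = stack[:, mask_arr]  # (n, n_vox)

    exhaustive = 2**n <= n_perm
    if exhaustive:
        n_used = 2**n
        bits = (np.arange(n_used)[:, None] >> np.arange(n)[None, :]) & 1
        signs = 1.0 - 2.0 * bits  # row 0 is all +1 (identity)
    else:
        n_used = n_perm
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        signs[0] = 1.0  # identity always included

    smoother = None
    if variance_smoothing_fwhm is not None and variance_smoothing_fwhm > 0:
        if grid is None:
            raise ValueError("variance smoothing needs a grid (pass VolumeImages)")
        sigma = _fwhm_to_sigma_vox(variance_smoothing_fwhm, grid.voxel_sizes)
        m = mask_arr.astype(float)
        norm = ndimage.gaussian_filter(m, sigma)

        def smoother(var_flat: np.ndarray) -> np.ndarray:
            out = np.empty_like(var_flat)
            for k in range(var_flat.shape[0]):
                vol = np.zeros(mask_arr.shape)
                vol[mask_arr] = var_flat[k]
                sm = ndimage.gaussian_filter(vol, sigma)
                with np.errstate(invalid="ignore", divide="ignore"):
                    sm = np.where(norm > 0, sm / norm, 0.0)
                out[k] = sm[mask_arr]
            return out

    # observed statistic is permutation row 0 in both branches
    t_all = _statistics(data, signs, smoother)
    t_obs = t_all[0]
    null_max = t_all.max(axis=1)  # (n_perm,)
    fwe = np.mean(null_max[:, None] >= t_obs[None, :], axis=0)

    if grid is None:
        raise ValueError("pass VolumeImage inputs (a grid is required)")
    t_vol = np.zeros(mask_arr.shape)
    t_vol[mask_arr] = t_obs
    p_vol = np.ones(mask_arr.shape)
    p_vol[mask_arr] = fwe
    return PermutationResult(
        pseudo_t=VolumeImage(grid, t_vol),
        fwe_p=VolumeImage(grid, p_vol),
        null_max_distribution=null_max,
        n_permutations_used=int(n_used),
        exhaustive=bool(exhaustive),
    )
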