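"""Shared fixtures and independent oracle helpers.

Oracles here are deliberately naive (explicit loops, direct formulas) and
never call the library code paths they are used to check.
"""

from __future__ import annotations

import numpy as np
import pytest

from tractolesion.grids import VolumeGrid, VolumeImage
from tractolesion.io import Tractogram


@pytest.fixture
def unit_grid():
    """10^3 grid with 1 mm voxels, voxel i at world coordinate i."""
    return VolumeGrid((10, 10, 10), np.eye(4))


@pytest.fixture
def mm2_grid():
    """16^3 grid, 2 mm voxels, centered so the x=0 plane is a mirror plane."""
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = -15.0
    return VolumeGrid((16, 16, 16), affine)


def straight_streamline(start, direction, n_points, spacing=1.0):
    """Equally spaced polyline from start along a unit direction."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    t = np.arange(n_points)[:, None] * spacing
    return np.asarray(start, float) + t * d


def mask_image(grid: VolumeGrid, voxels) -> VolumeImage:
    """Binary VolumeImage with the given voxel indices set."""
    data = np.zeros(grid.dims, dtype=np.uint8)
    for v in voxels:
        data[tuple(v)] = 1
    return VolumeImage(grid, data)


def random_tractogram(grid: VolumeGrid, rng: np.random.Generator, n_streamlines: int):
    """Random dense polylines inside the grid (max step 0.5 voxel)."""
    lo = grid.voxel_to_world(np.zeros(3))
    hi = grid.voxel_to_world(np.array(grid.dims, float) - 1)
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    streamlines = []
    max_step = 0.5 * float(grid.voxel_sizes.min())
    for _ in range(n_streamlines):
        n = rng.integers(2, 40)
        start = rng.uniform(lo, hi)
        steps = rng.uniform(-max_step, max_step, size=(n - 1, 3))
        pts = np.clip(start + np.vstack([np.zeros(3), np.cumsum(steps, 0)]), lo, hi)
        streamlines.append(pts)
    return Tractogram(streamlines, grid)


# ----------------------------------------------------------------- oracles


def oracle_select(tractogram: Tractogram, lesion_data: np.ndarray) -> list[int]:
    """Brute force: loop over every point of every streamline."""
    grid = tractogram.grid
    inv = np.linalg.inv(grid.affine)
    hit = []
    for i, s in enumerate(tractogram.streamlines):
        for p in s:
            v = np.floor(inv[:3, :3] @ p + inv[:3, 3] + 0.5).astype(int)
            if np.all(v >= 0) and np.all(v < grid.dims):
                if lesion_data[tuple(v)] > 0:
                    hit.append(i)
                    break
    return hit


def oracle_polyline_distances(points: np.ndarray, lesion_hits: np.ndarray) -> np.ndarray:
    """Per-point arc distance to nearest flagged point, by explicit loops."""
    seg = [0.0]
    for a, b in zip(points[:-1], points[1:]):
        seg.append(seg[-1] + float(np.linalg.norm(b - a)))
    arc = np.array(seg)
    les = arc[lesion_hits]
    return np.array([min(abs(a - l) for l in les) for a in arc])


def oracle_rm_anova_ss(y: np.ndarray) -> dict:
    """Sums of squares for a (n, a, b) within-subject design, pure loops."""
    n, a, b = y.shape
    gm = y.mean()
    ss = dict(subj=0.0, A=0.0, B=0.0, AB=0.0, AS=0.0, BS=0.0, total=0.0)
    m_s = [y[s].mean() for s in range(n)]
    m_a = [y[:, i].mean() for i in range(a)]
    m_b = [y[:, :, j].mean() for j in range(b)]
    for s in range(n):
        ss["subj"] += a * b * (m_s[s] - gm) ** 2
    for i in range(a):
        ss["A"] += n * b * (m_a[i] - gm) ** 2
    for j in range(b):
        ss["B"] += n * a * (m_b[j] - gm) ** 2
    for i in range(a):
        for j in range(b):
            ss["AB"] += n * (y[:, i, j].mean() - m_a[i] - m_b[j] + gm) ** 2
    for s in range(n):
        for i in range(a):
            ss["AS"] += b * (y[s, i].mean() - m_s[s] - m_a[i] + gm) ** 2
        for j in range(b):
            ss["BS"] += a * (y[s, :, j].mean() - m_s[s] - m_b[j] + gm) ** 2
    for s in range(n):
        for i in range(a):
            for j in range(b):
                ss["total"] += (y[s, i, j] - gm) ** 2
    ss["ABS"] = ss["total"] - sum(ss[k] for k in ("subj", "A", "B", "AB", "AS", "BS"))
    return ss


def oracle_sign_flip(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exhaustive sign-flip one-sample t via explicit loops.

    data: (n_subjects, n_voxels).  Returns (t_observed, fwe_p, null_max)
    over all 2^n sign assignments, identity first.
    """
    import itertools

    n, _ = data.shape
    t_rows = []
    for signs in itertools.product([1.0, -1.0], repeat=n):
        flipped = np.array(signs)[:, None] * data
        m = flipped.mean(axis=0)
        sd = flipped.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = m / (sd / np.sqrt(n))
        t[~np.isfinite(t)] = 0.0
        t_rows.append(t)
    t_all = np.array(t_rows)
    t_obs = t_all[0]
    null_max = t_all.max(axis=1)
    fwe = np.mean(null_max[:, None] >= t_obs[None, :], axis=0)
    return t_obs, fwe, null_max
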