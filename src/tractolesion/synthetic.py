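"""Synthetic phantoms: fiber-bundle tractogram databases, lesions, and
two-timepoint diffusion maps with known ground truth.

The generator emulates the inputs the pipeline consumes in practice -- a
normative tractography database (multiple pseudo-subjects whose bundle
centerlines are jittered subject-to-subject), a focal lesion intersecting
a bundle, and eigenvalue maps for two post-injury timepoints with injected
within-bundle degeneration (an early axial-diffusivity decrease, a later
radial-diffusivity increase) plus additive noise -- so recovery of the
injected effect sizes can be checked end to end.

Default conditions: a 48-voxel cubic 2-mm grid; one pseudo-CST bundle per
hemisphere plus one crossing transverse bundle (2000 streamlines per
subject in total), 20 database subjects; baseline eigenvalues
(1.7, 0.4, 0.3)x10^-3 mm^2/s inside bundles (FA ~ 0.74) over an isotropic
0.8x10^-3 background; a 6-mm spherical lesion on the right bundle; lambda1
factor 0.94 at week 6, lambda1 0.98 and lambda23 1.07 at week 29; 5 %
proportional Gaussian noise on the eigenvalue maps.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .damage import LesionMask
from .dti import (
    DiffusionScalarSet,
    GradientTable,
    TensorVolume,
    predict_signal,
    scalar_set_from_eigenvalues,
)
from .grids import VolumeGrid, VolumeImage
from .io import Tractogram

__all__ = [
    "BundleSpec",
    "DegenerationProfile",
    "make_phantom_database",
    "make_lesion",
    "make_diffusion_maps",
    "make_gradient_scheme",
    "synthesize_dwi",
    "arc_coordinate_map",
    "default_grid",
    "default_bundles",
    "default_lesion",
    "default_profile",
]

BASELINE_BUNDLE = (1.7e-3, 0.4e-3, 0.3e-3)  # mm^2/s, white matter
BASELINE_BACKGROUND = 0.8e-3  # isotropic grey-matter-like background


def _orthonormal_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing ``u`` to a right-handed frame."""
    u = u / np.linalg.norm(u)
    helper = np.eye(3)[np.argmin(np.abs(u))]
    v = np.cross(u, helper)
    v /= np.linalg.norm(v)
    return v, np.cross(u, v)


@dataclass(frozen=True)
class BundleSpec:
    """A tube of streamlines around a parametric centerline.

    The centerline is a straight segment, a planar circular arc, or a
    helix; streamlines are parallel offset copies sampled uniformly in the
    tube cross-section (disk of ``radius`` mm), with one Gaussian
    whole-centerline jitter per database subject (``jitter_sd`` mm per
    axis).  ``point_spacing`` must not exceed half the smallest voxel edge
    so that point-sampled voxelization cannot skip voxels.
    """

    name: str
    kind: str  # "straight" | "arc" | "helix"
    radius: float
    n_streamlines: int
    point_spacing: float
    jitter_sd: float
    grid: VolumeGrid
    # straight
    start: tuple[float, float, float] | None = None
    end: tuple[float, float, float] | None = None
    # arc / helix: center, orthonormal in-plane axes u, v, arc radius,
    # angular range; helix additionally rises along u x v
    arc_center: tuple[float, float, float] | None = None
    arc_u: tuple[float, float, float] | None = None
    arc_v: tuple[float, float, float] | None = None
    arc_radius: float | None = None
    theta_range: tuple[float, float] | None = None
    helix_pitch: float = 0.0  # mm of rise per full turn

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"bundle {self.name!r}: radius must be > 0")
        if self.point_spacing > 0.5 * float(self.grid.voxel_sizes.min()) + 1e-12:
            raise ValueError(
                f"bundle {self.name!r}: point_spacing must be <= half the "
                "smallest voxel edge"
            )
        if self.kind == "straight":
            if self.start is None or self.end is None:
                raise ValueError(f"straight bundle {self.name!r} needs start and end")
        elif self.kind in ("arc", "helix"):
            for f in ("arc_center", "arc_u", "arc_v", "arc_radius", "theta_range"):
                if getattr(self, f) is None:
                    raise ValueError(f"{self.kind} bundle {self.name!r} needs {f}")
        else:
            raise ValueError(f"unknown bundle kind {self.kind!r}")

    @property
    def length(self) -> float:
        """Analytic centerline arc length (mm)."""
        if self.kind == "straight":
            return float(np.linalg.norm(np.subtract(self.end, self.start)))
        dtheta = abs(self.theta_range[1] - self.theta_range[0])
        if self.kind == "arc":
            return float(self.arc_radius * dtheta)
        rise = self.helix_pitch / (2 * np.pi)
        return float(dtheta * np.hypot(self.arc_radius, rise))

    @property
    def n_points(self) -> int:
        return int(round(self.length / self.point_spacing)) + 1

    def _frames(self, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Centerline points plus per-point cross-section axes (e1, e2)."""
        if self.kind == "straight":
            start = np.asarray(self.start, float)
            end = np.asarray(self.end, float)
            t = np.linspace(0.0, 1.0, n)[:, None]
            pts = start + t * (end - start)
            v, w = _orthonormal_frame(end - start)
            e1 = np.broadcast_to(v, (n, 3))
            e2 = np.broadcast_to(w, (n, 3))
            return pts, e1, e2
        c = np.asarray(self.arc_center, float)
        u = np.asarray(self.arc_u, float)
        v = np.asarray(self.arc_v, float)
        w = np.cross(u, v)
        theta = np.linspace(*self.theta_range, n)
        e_r = np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v
        pts = c + self.arc_radius * e_r
        if self.kind == "helix":
            pts = pts + (self.helix_pitch * theta / (2 * np.pi))[:, None] * w
        e2 = np.broadcast_to(w, (n, 3))
        return pts, e_r, e2

    def sample_centerline(self, spacing: float | None = None) -> np.ndarray:
        """Centerline polyline at ``spacing`` (default: point_spacing)."""
        if spacing is None:
            n = self.n_points
        else:
            n = int(round(self.length / spacing)) + 1
        return self._frames(n)[0]

    def sample_streamlines(self, rng: np.random.Generator) -> list[np.ndarray]:
        """One subject's streamlines: tube offsets + centerline jitter."""
        n = self.n_points
        pts, e1, e2 = self._frames(n)
        jitter = rng.normal(0.0, self.jitter_sd, size=3) if self.jitter_sd > 0 else 0.0
        # uniform in the cross-section disk
        r = self.radius * np.sqrt(rng.random(self.n_streamlines))
        phi = 2 * np.pi * rng.random(self.n_streamlines)
        a, b = r * np.cos(phi), r * np.sin(phi)
        return [
            pts + a[i] * e1 + b[i] * e2 + jitter
            for i in range(self.n_streamlines)
        ]

    def check_inside_grid(self, margin: float) -> None:
        """Error (naming the bundle) if the tube can leave the grid."""
        vox = self.grid.world_to_voxel_continuous(self.sample_centerline())
        m = (self.radius + margin) / float(self.grid.voxel_sizes.min())
        lo_ok = np.all(vox >= -0.5 + m)
        hi_ok = np.all(vox <= np.array(self.grid.dims) - 0.5 - m)
        if not (lo_ok and hi_ok):
            raise ValueError(f"bundle {self.name!r} leaves the grid")


@dataclass(frozen=True)
class DegenerationProfile:
    """Injected within-bundle effects per timepoint, plus map noise.

    ``factors[timepoint][metric]`` is the multiplicative effect applied to
    the affected bundle's ipsilesional voxels ("lambda1" scales the largest
    eigenvalue, "lambda23" the two smaller ones).  ``distance_slopes``
    optionally adds a per-mm linear term, so the local multiplier is
    ``factor + slope * distance_from_lesion``.  ``noise_sd`` is the
    standard deviation of additive Gaussian noise as a fraction of each
    eigenvalue's local noise-free value.
    """

    factors: dict = field(
        default_factory=lambda: {
            "W6": {"lambda1": 0.94, "lambda23": 1.00},
            "W29": {"lambda1": 0.98, "lambda23": 1.07},
        }
    )
    distance_slopes: dict = field(default_factory=dict)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for tp, fx in self.factors.items():
            for metric, f in fx.items():
                if f <= 0:
                    raise ValueError(f"factor {metric}@{tp} must be > 0, got {f}")

    def multiplier(self, timepoint: str, metric: str, distance: np.ndarray) -> np.ndarray:
        if timepoint not in self.factors:
            raise KeyError(f"profile defines no factors for timepoint {timepoint!r}")
        base = self.factors[timepoint].get(metric, 1.0)
        slope = self.distance_slopes.get(timepoint, {}).get(metric, 0.0)
        return base + slope * np.asarray(distance, float)


def make_phantom_database(
    bundles: list[BundleSpec], n_subjects: int, seed: int = 0
) -> list[Tractogram]:
    """Tractograms for ``n_subjects`` pseudo-subjects, deterministic in seed."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not bundles:
        raise ValueError("need at least one bundle")
    grid = bundles[0].grid
    for b in bundles:
        grid.require_match(b.grid, "bundles")
        b.check_inside_grid(margin=4.0 * b.jitter_sd)
    subjects = []
    for s in range(n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), s]))
        streamlines: list[np.ndarray] = []
        for b in bundles:
            streamlines.extend(b.sample_streamlines(rng))
        subjects.append(Tractogram(streamlines, grid))
    return subjects


def make_lesion(
    center: tuple[float, float, float], radius: float, grid: VolumeGrid
) -> LesionMask:
    """Spherical lesion: voxels whose centers lie within ``radius`` of
    ``center`` (world mm); side inferred from the center's x sign."""
    centers = _voxel_centers(grid)
    inside = np.linalg.norm(centers - np.asarray(center, float), axis=1) <= radius
    if not inside.any():
        raise ValueError("lesion sphere contains no voxel center")
    data = inside.reshape(grid.dims).astype(np.uint8)
    side = "right" if center[0] > 0 else "left"
    return LesionMask(VolumeImage(grid, data), side)


def _voxel_centers(grid: VolumeGrid) -> np.ndarray:
    idx = np.indices(grid.dims).reshape(3, -1).T
    return grid.voxel_to_world(idx)


def _centerline_distance(grid: VolumeGrid, bundle: BundleSpec) -> np.ndarray:
    """Per-voxel Euclidean distance (mm) to the bundle centerline."""
    tree = cKDTree(bundle.sample_centerline(spacing=0.5))
    d, _ = tree.query(_voxel_centers(grid))
    return d.reshape(grid.dims)


def arc_coordinate_map(bundle: BundleSpec, grid: VolumeGrid) -> np.ndarray:
    """Arc-length coordinate (mm) of each voxel's centerline projection.

    For a straight bundle this is the signed distance of the voxel center's
    projection from the start point; for arcs/helices, arc length to the
    nearest densely sampled centerline point.  Used to build analytic
    along-fiber distance maps for injection and validation.
    """
    spacing = 0.25
    cl = bundle.sample_centerline(spacing=spacing)
    seg = np.linalg.norm(np.diff(cl, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    tree = cKDTree(cl)
    _, nearest = tree.query(_voxel_centers(grid))
    return arc[nearest].reshape(grid.dims)


def make_diffusion_maps(
    bundles: list[BundleSpec],
    lesion: LesionMask,
    profile: DegenerationProfile,
    timepoint: str,
    distance_map: np.ndarray | VolumeImage | None = None,
    tissue_margin: float = 4.0,
    baseline_bundle: tuple[float, float, float] = BASELINE_BUNDLE,
    baseline_background: float = BASELINE_BACKGROUND,
    rng: np.random.Generator | None = None,
) -> tuple[DiffusionScalarSet, dict]:
    """Eigenvalue maps for one timepoint with injected degeneration.

    Bundle voxels (within ``radius + tissue_margin`` mm of a centerline)
    get anisotropic baseline eigenvalues, the rest the isotropic
    background.  Voxels of lesion-affected bundles on the lesion side only
    are multiplied by the profile's factors (optionally distance-modulated
    via ``distance_map``); the contralesional mirror stays at baseline.
    Proportional Gaussian noise is then added and eigenvalues re-sorted.

    Returns the scalar set and a ground-truth dict (per-voxel multiplier
    maps, affected/tissue masks).
    """
    grid = lesion.grid
    if rng is None:
        tp_tag = zlib.crc32(timepoint.encode()) % (2**31)  # stable across runs
        rng = np.random.default_rng(np.random.SeedSequence([int(profile.seed), tp_tag]))

    tissue = np.zeros(grid.dims, dtype=bool)
    affected = np.zeros(grid.dims, dtype=bool)
    lesion_centers = grid.voxel_to_world(np.argwhere(np.asarray(lesion.volume.data) > 0))
    xs = _voxel_centers(grid)[:, 0].reshape(grid.dims)
    ipsi = xs > 0 if lesion.side == "right" else xs < 0
    for b in bundles:
        grid.require_match(b.grid, "lesion and bundles")
        dist = _centerline_distance(grid, b)
        in_tube = dist <= b.radius + tissue_margin
        tissue |= in_tube
        tree = cKDTree(b.sample_centerline(spacing=0.5))
        hit = tree.query(lesion_centers)[0].min() <= b.radius + tissue_margin
        if hit:
            affected |= in_tube & ipsi

    l1 = np.full(grid.dims, baseline_background)
    l2 = np.full(grid.dims, baseline_background)
    l3 = np.full(grid.dims, baseline_background)
    l1[tissue], l2[tissue], l3[tissue] = baseline_bundle

    if distance_map is None:
        d = np.zeros(grid.dims)
    else:
        d = np.asarray(
            distance_map.data if isinstance(distance_map, VolumeImage) else distance_map,
            float,
        )
        d = np.where(np.isnan(d), 0.0, d)

    m_l1 = np.ones(grid.dims)
    m_l23 = np.ones(grid.dims)
    m_l1[affected] = profile.multiplier(timepoint, "lambda1", d)[affected]
    m_l23[affected] = profile.multiplier(timepoint, "lambda23", d)[affected]
    l1 = l1 * m_l1
    l2 = l2 * m_l23
    l3 = l3 * m_l23

    if profile.noise_sd > 0:
        l1 = l1 + rng.normal(0.0, profile.noise_sd * np.abs(l1))
        l2 = l2 + rng.normal(0.0, profile.noise_sd * np.abs(l2))
        l3 = l3 + rng.normal(0.0, profile.noise_sd * np.abs(l3))
        lam = np.sort(np.stack([l1, l2, l3], axis=-1), axis=-1)[..., ::-1]
        l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]

    truth = {
        "multiplier_lambda1": m_l1,
        "multiplier_lambda23": m_l23,
        "affected_mask": affected,
        "tissue_mask": tissue,
    }
    return scalar_set_from_eigenvalues(grid, l1, l2, l3), truth


def make_gradient_scheme(
    n_directions: int = 32, bval: float = 800.0, n_b0: int = 1
) -> GradientTable:
    """Deterministic gradient scheme: Fibonacci-sphere directions + b=0s."""
    i = np.arange(n_directions)
    golden = (1 + np.sqrt(5)) / 2
    z = 1 - (2 * i + 1) / n_directions
    r = np.sqrt(np.maximum(1 - z**2, 0))
    phi = 2 * np.pi * i / golden
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(bval))])
    return GradientTable(bvecs, bvals)


def synthesize_dwi(
    tensor: TensorVolume,
    gradients: GradientTable,
    s0: float = 1000.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Forward DWI signals S = S0 exp(-b g'Dg), optionally with Rician noise."""
    sig = predict_signal(tensor.components, gradients, s0=s0)
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        re = sig + rng.normal(0, noise_sd * s0, sig.shape)
        im = rng.normal(0, noise_sd * s0, sig.shape)
        sig = np.hypot(re, im)
    return sig


# ---------------------------------------------------------------- defaults


def default_grid() -> VolumeGrid:
    """48^3 voxels, 2 mm isotropic, centered on x=0 so mirroring is exact."""
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = -47.0
    return VolumeGrid((48, 48, 48), affine)


def default_bundles(
    grid: VolumeGrid | None = None,
    n_streamlines_cst: int = 800,
    n_streamlines_transverse: int = 400,
) -> list[BundleSpec]:
    """One pseudo-CST per hemisphere plus a crossing transverse bundle."""
    grid = grid or default_grid()
    common = dict(
        radius=4.0, point_spacing=1.0, jitter_sd=0.5, grid=grid, kind="straight"
    )
    return [
        BundleSpec(
            name="cst_right", start=(24.0, 0.0, -40.0), end=(24.0, 0.0, 40.0),
            n_streamlines=n_streamlines_cst, **common,
        ),
        BundleSpec(
            name="cst_left", start=(-24.0, 0.0, -40.0), end=(-24.0, 0.0, 40.0),
            n_streamlines=n_streamlines_cst, **common,
        ),
        BundleSpec(
            name="transverse", start=(-40.0, 0.0, 20.0), end=(40.0, 0.0, 20.0),
            n_streamlines=n_streamlines_transverse, **common,
        ),
    ]


def default_lesion(grid: VolumeGrid | None = None) -> LesionMask:
    """6-mm spherical lesion on the right pseudo-CST, below the crossing."""
    return make_lesion((24.0, 0.0, -10.0), 6.0, grid or default_grid())


def default_profile(seed: int = 0, noise_sd: float = 0.05) -> DegenerationProfile:
    return DegenerationProfile(noise_sd=noise_sd, seed=seed)
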