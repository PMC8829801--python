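# Methods

This note documents the models and procedures implemented in
`tractolesion`, the conventions chosen where several were defensible, and
what the synthetic phantoms do and do not establish about real data.

## Coordinate contract

All spatial objects in one analysis share a single `VolumeGrid` (voxel
dimensions + an invertible 4×4 voxel→world affine). Streamlines are
always stored in world mm; TRK files, which store voxel-scaled
coordinates on disk, are normalized to world mm at read time via the
header transform (TCK files carry no grid and require one explicitly).
A world point belongs to the voxel `floor(A⁻¹p + ½)` component-wise —
the nearest-voxel rule, 0-based. Points on an exact voxel boundary are
assigned by this rounding; no authoritative convention exists for the
boundary case, so it is stated here rather than assumed elsewhere.
Grids must agree to 1e-4 in the affine; mismatches are hard errors —
the package never reslices, because spatial normalization belongs
upstream of it.

## Damage model

**Selection.** A streamline is damaged iff ≥ 1 of its points falls in a
lesion voxel. Because selection is point-based, tractograms must be
densely sampled; the synthetic generator enforces a maximum point spacing
of half the smallest voxel edge so no traversed voxel can be skipped.
For the same reason voxelization of a streamline uses its sampled points
only, with no supercover line rasterization.

**Count volume.** A streamline contributes at most 1 to each voxel it
traverses, however many of its points fall there. Counting points
instead would make the volume depend on the tracking step size, which is
an acquisition artifact, not anatomy.

**Distance volume.** Per streamline, each point's distance to the lesion
is the arc length (cumulative Euclidean segment length along the
polyline) to the nearest of that same streamline's lesion-interior
points — the minimum over lesion crossings, so lesions crossed twice are
handled. Per voxel and streamline the minimum over the streamline's
points in that voxel is taken; per voxel the mean over traversing
streamlines. Voxels traversed by no damaged streamline hold NaN in
memory and −1 on disk (noted in the NIfTI description field). The
min-then-mean combination is this package's choice of a least-biased
monotone summary; the aggregation is deliberately isolated in
`distance_volume` / `average_models` so alternatives can be swapped in.

**Database averaging.** Counts are averaged arithmetically over all
database subjects, zeros included. Distances are averaged with
count weights (subjects contributing more damaged streamlines to a voxel
weigh more), and remain undefined where every subject's count is zero.

**Hemisphere standardization.** Models of patients with a right-sided
deficit (left-hemisphere lesion) are mirrored index-wise i → Nx−1−i along
the first (left–right) axis, so the lesioned hemisphere is on the right
for every subject before group analysis. The flip is an involution and
preserves the voxel-value multiset exactly.

## Diffusion scalars

Tensors are fitted voxel-wise by ordinary least squares on
log(S/S₀) = −b gᵀDg — plain log-linear LS, no weighting, no positivity
constraint. This is the simplest fully testable baseline: it inverts the
noise-free forward model exactly for any SPD tensor (verified to 1e-9),
and its noise behaviour is characterized by Monte Carlo in the tests.
Negative eigenvalues from noisy fits are kept; downstream ROI
construction removes unreliable voxels through the FA floor rather than
by clipping, which would bias the scalars.

Eigenvalues are extracted with a batched symmetric eigendecomposition
and sorted descending. Scalars use the standard definitions
MD = (λ₁+λ₂+λ₃)/3, RD = λ₂₃ = (λ₂+λ₃)/2 and
FA = √(½ Σᵢ<ⱼ (λᵢ−λⱼ)² / Σ λᵢ²), with FA defined as 0 at all-zero voxels.
FA is scale-invariant and bounded in [0, 1] for non-negative eigenvalues;
both properties are enforced by bulk randomized tests.

## ROI analysis

The tract ROI is `count > count_threshold AND NOT lesion AND
FA ≥ fa_floor`, with defaults count_threshold = 3 (strict inequality,
so a voxel with exactly 3 damaged fibers is excluded) and
fa_floor = 0.1. The FA exclusion uses one timepoint's FA map (by default
the first supplied) and the ROI is then held fixed across timepoints, so
longitudinal comparisons always average identical voxels; using
per-timepoint ROIs would confound change in the metric with change in
the ROI. The contralesional reference is the exact left–right mirror of
the tract ROI, and each distance bin's reference is the mirror of that
bin.

Distance bins are half-open intervals [lo, hi) over the model's distance
volume, default edges 0, 10, 20, 30, 40, 50 mm; half-open intervals
avoid double-counting boundary voxels. Voxels beyond the last edge or
with undefined distance belong to no bin (the count is logged). Bin
disjointness and containment in the tract ROI are asserted on every
construction.

Per ROI and metric the table reports the ipsilesional mean, the
contralesional mean over the mirrored ROI, and their ratio; a zero
contralesional mean flags the ratio undefined rather than emitting an
infinity.

## Group statistics

Paired comparisons are gated by a Shapiro–Wilk test on the paired
differences at α = .05: Gaussian-looking differences use the paired t
test, otherwise the Wilcoxon signed-rank test (zero differences dropped,
ties mid-ranked, T = smaller signed-rank sum, z from the tie-corrected
normal approximation). The gate is a pragmatic stand-in for an
unspecified normality check; both tests are always computable directly
and the branch taken is recorded.

The two-way repeated-measures ANOVA decomposes a complete balanced
(subject × factor A × factor B) array with subject-interaction error
terms: F_A = MS_A / MS_{A×S} on df (a−1), (a−1)(n−1), analogously for B
and A×B. No sphericity correction is applied by default (matching the
uncorrected df convention of two-level factors, where sphericity is
moot); an optional Greenhouse–Geisser correction (`correction="gg"`)
scales each effect's df pair by its epsilon, computed from the
covariance of the effect-projected per-subject scores. Total SS
conservation is checked to 1e-9 and the decomposition — including the
epsilon values — is cross-validated against both an explicit-loop oracle
and `pingouin.rm_anova`. Effect SS below 1e-12 of the total SS are treated
as exact zeros so degenerate (flat) designs report F = 0 rather than
round-off ratios.

The one-sample permutation test flips each subject's image by ±1,
recomputes the voxelwise t (optionally a pseudo-t whose variance image
is Gaussian-smoothed within the mask — off by default, since an
unverifiable smoothing kernel should not silently shape results), and
uses the image-wide maximum as the null for FWE-corrected p-values.
When 2ⁿ ≤ n_perm all 2ⁿ assignments are enumerated exactly
(deterministic, seed-independent); otherwise the identity plus
n_perm − 1 random flips. The identity assignment is always included, so
the smallest attainable p is 1/n_perm. For n = 11 subjects a request of
2048 permutations is exactly exhaustive.

## Synthetic phantoms

The generator emulates the pipeline's real inputs at desk scale:

- **Grid**: 48³ voxels, 2 mm isotropic, centered so the x = 0 plane is an
  exact mirror plane (mirroring never resamples).
- **Bundles**: one straight pseudo-CST per hemisphere (length 80 mm,
  tube radius 4 mm, 800 streamlines, 1-mm point spacing) plus one
  crossing transverse bundle (400 streamlines) — 2000 streamlines per
  subject. Streamlines are parallel offsets uniform in the tube
  cross-section; each database subject's centerlines get one Gaussian
  jitter (SD 0.5 mm/axis). Arc and helix centerlines are available for
  curvature-sensitive tests. Default database: 20 subjects.
- **Lesion**: 6-mm sphere on the right bundle, 30 mm from its start.
- **Eigenvalue maps**: bundle voxels (1.7, 0.4, 0.3)×10⁻³ mm²/s
  (FA ≈ 0.74, well above the 0.1 floor), isotropic 0.8×10⁻³ background —
  typical white-/grey-matter literature values, configurable. Injected
  degeneration multiplies eigenvalues of the lesion-side affected bundle
  only: λ₁ ×0.94 at "W6", λ₁ ×0.98 and λ₂₃ ×1.07 at "W29" by default —
  the early axial decrease and later radial increase pattern of
  secondary degeneration; effect sizes are free parameters. Factors can
  vary linearly with along-fiber distance. Noise is additive Gaussian
  per eigenvalue map with SD proportional (default 5 %) to the local
  noise-free value, and eigenvalues are re-sorted afterwards.

The tissue assignment extends the nominal tube radius by a 4-mm margin
so every voxel the jittered streamlines can reach carries bundle
eigenvalues; this makes noise-free ratio recovery exact and is the
reason the phantom's recovered ratios equal the injected factors to
1e-9.

**What the phantom does not show.** It has no crossing-fiber partial
voluming inside the tensor model, no susceptibility or motion artifacts,
no registration error, no lesion-adjacent edema, and Gaussian rather
than Rician map noise (Rician noise exists only in the optional DWI
synthesis path). Passing phantom tests therefore demonstrates the
correctness of the selection/count/distance/ROI/statistics machinery,
not robustness to the acquisition and registration imperfections of
clinical data.

## Problem sizes and determinism

The shipped test and acceptance runs use the default phantom (20
subjects × 2000 streamlines, 48³ grid), 20 noise realizations for ratio
recovery, and 500 replicates for the permutation-calibration check —
sizes chosen so the statistical targets (±2 % ratio recovery; empirical
FWE inside the 95 % binomial band around .05) are well resolved while a
complete run stays in the minutes range. All randomness flows through
explicit seeds (`numpy.random.SeedSequence`); database generation,
noisy-map synthesis, and the non-exhaustive permutation branch are
bit-reproducible given a seed, and the file pipeline writes uncompressed
NIfTI so reruns are byte-identical (gzip embeds timestamps).

## Known limitations

- Streamline-voxel membership is point-sampled; tractograms with step
  sizes larger than half a voxel edge can skip traversed voxels. Inputs
  of that kind should be resampled upstream.
- The count-weighted distance averaging and min-then-mean per-voxel
  summary are reasonable but not canonical; alternative summaries
  (e.g. per-point means) would shift distance values by up to a voxel.
- `fit_tensor_lls` is unweighted; at very low SNR, weighted or robust
  variants would outperform it.
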