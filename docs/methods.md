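# Methods

This note documents the models, parameter choices, and numerical decisions
behind `octamnv`, and what the synthetic phantoms do and do not establish
about behavior on clinical scans.

## Coordinate and unit conventions

`x` is the fast axis (A-scan position within a B-scan), `y` the B-scan
index, `z` depth increasing posteriorly; volumes are `(nz, ny, nx)`.
Surfaces store the boundary's axial position in µm from the first
(anterior) voxel plane, so an elevated RPE has *smaller* z than Bruch's
membrane and PED height is `max(0, z_BM − z_RPE)`. Depths, pitches, and
thicknesses are in µm; areas and volumes are converted to mm²/mm³ only
when scalar metrics are emitted. Monthly rates divide by a 30.44-day month
(365.25/12); the "at least 6 months" buffer for selecting stable visit
pairs is 183 days. All 2-D connected components use 8-connectivity.
The signal-strength quality gate (default minimum 7) is a metadata check at
read time, not an image-based estimator, since it acts as an exclusion
criterion rather than a computation.

## Slab extraction and preprocessing

Slabs are defined by surface + offset pairs; the presets are the ORCC slab
(outer retinal boundary down to BM + 4 µm) and the 16-µm CC slab starting
4 µm beneath BM. The ORCC bottom is resolved as BM + 4 µm so the two slabs
abut without gap or overlap. Mean projection integrates the
piecewise-constant A-scan profile between the boundaries, so sub-voxel
offsets are resolved linearly; a slab that leaves the volume fails when
more than 1% of the requested depth is clipped. Mean projection is used
for both flow and structure slabs: for thin slabs it is robust to single
bright voxels, where a max projection would be noise-seeking.

Projection-artifact removal is mask-and-inpaint: pixels under the supplied
retinal-vessel mask are replaced by harmonic (iterative 8-neighbor mean)
interpolation with the unmasked pixels as boundary conditions. The exact
published operator behind artifact removal is not specified at this level
of detail, so this contract — non-masked pixels untouched, idempotent,
constant fields preserved — is a documented, testable stand-in.

Structural compensation divides the CC flow image by the en face structure
smoothed with a 3-px Gaussian, floored at its 1st percentile, normalized to
its mean; the output is rescaled to preserve mean flow. The formula is one
published reading of slab-based compensation and sits behind a single
function so an alternative can be swapped in. It is exactly equivariant to
global rescaling of the structure image.

## Lesion detection and metrics

`segment_mnv` thresholds the artifact-removed ORCC image at background
mean + 2 SD, where the background statistics come from pixels more than
600 µm away from an Otsu-provisional foreground (this keeps lesion flow out
of the estimate), followed by morphological closing (disk radius 2 px),
hole filling, and removal of components below 0.01 mm². The published
lesion-detection algorithm is proprietary to the instrument vendor's
pipeline; this transparent substitute is validated on phantoms (area error
≤ 5% at the tested noise level across 20 seeds; Dice ≥ 0.95 noise-free).

The greatest linear dimension is the maximal pairwise distance between
boundary-pixel centers (convex-hull accelerated, brute force on degenerate
point sets). Focus counting merges components whose boundary-to-boundary
Euclidean distance is under 600 µm — the criterion that two foci are
discrete only when their 300-µm rims do not overlap — via union–find over
pairwise distance-transform minima.

## Choriocapillaris flow deficits

Regions are built from the Euclidean distance transform of the lesion mask
with anisotropic pixel pitches: R1 is 0 < d ≤ 300 µm, R2 is
300 < d ≤ 600 µm, R3 the remainder excluding the lesion; an empty lesion
makes the whole scan R3. Membership is by pixel center, and the four
labels always partition the scan.

The default global threshold is per-image mean − 1 SD computed over the
analyzed area excluding the MNV; a fixed absolute threshold ("normative"
mode) is available because the literature uses both and the normative
constant is instrument-specific. Deficits are pixels *strictly below* the
threshold, which makes deficit count monotone in a fixed threshold. The
small-deficit filter removes components with equivalent diameter
2·√(A/π) < 24 µm, i.e. area < π·12² ≈ 452.39 µm²; at 12-µm pitch this
removes ≤ 3-px components and keeps ≥ 4-px ones. It is idempotent and can
only lower FD%. Mean FD area averages components *clipped to each region*
(a straddling deficit contributes its parts to each side), keeping the
numerator consistent with the region's own denominator.

## Vascularity

The lesion-masked flow image feeds two detectors whose union is the binary
vessel map: a multiscale Hessian tubularity filter (Sato vesselness,
scales 1–2 px, Otsu-thresholded within the lesion) and local-mean adaptive
thresholding (33-px window, offset 0.25 of the intra-lesion dynamic range
above the local mean). The union reading of "combined use" keeps thin
vessels (Hessian) and wide trunks (adaptive); intersection is available as
an option. Scales of 1–2 px match capillary-scale vessels at 12-µm
sampling — a 3-px-wide tube is blurred, not enhanced, by a 3-px-scale
kernel, which measurably degraded phantom recovery. The map is despeckled
(< 3-px components removed) and skeletonized by topology-preserving
thinning. VAD and VSD are pixel-count ratios over the lesion area;
skeleton length is a pixel count, not a √2-weighted arc length, because
the published densities are unitless pixel ratios.

## PED volumetry

Height = max(0, BM − RPE) per pixel; area counts pixels above the
`min_height_um` floor (default 0 — any positive elevation counts, since the
manufacturer algorithm's floor is unpublished), and volume integrates
height × pixel area with exact µm→mm conversion. MNV–PED metrics zero the
height map outside the lesion mask, excluding drusen. Surfaces are taken
as authoritative; no re-segmentation or smoothing is applied before
integration.

## Choroid

Attenuation compensation is per A-scan
`I_c(z) = I(z)^n / (2·Σ_{z'>z} I(z')^n·Δz + ε)` with n = 1 and
ε = 10⁻⁶ of the maximum (the reference constants being unpublished, both
are config keys), rescaled to the input dynamic range. Thickness is
CSI − BM per A-scan; MCT averages it over pixels whose centers lie within
2.5 mm of the fovea (no partial-pixel weighting; ≤ 0.2% area error at
12-µm pitch), and the computation refuses a circle clipped by the scan
edge. Vessels are segmented by inverting the slab intensities (choroidal
vessels are dark on structural OCT) and applying one Otsu threshold to the
histogram of *all* slab voxels — a global threshold, not per B-scan
(per-B-scan is available for sensitivity analysis). CVI is vessel voxels
over slab voxels inside the circle, identical to the slab-voxel-weighted
mean of the per-A-scan fraction map.

For clinical scans the pipeline compensates before Otsu by default, since
shadowing otherwise biases the vessel class. The recovery tests and the
acceptance script segment the *raw* phantom volumes instead: the two-valued
phantom contains no depth attenuation, so compensation would introduce an
artificial depth gradient that the real algorithm is designed to remove,
not add. This is a limitation of the phantom, not of the measurement:
what the tests establish is correct thresholding, slab bookkeeping, and
circle geometry, not shadow correction on real tissue (which is exercised
separately by a constructed shadow test).

## Statistics

Between-group differences are reported as no-exudation minus exudation.
The 95% CI uses the equal-variance pooled-*t* construction
(`sp² = ((n₁−1)s₁² + (n₂−1)s₂²)/df`, df = n₁+n₂−2), which reproduces the
published intervals from the printed group means/SDs at n = 12/9 exactly
to table precision; Welch is available behind a flag. When Shapiro–Wilk
rejects normality in either group at α = 0.05 (per-group by default;
pooled-residual mode available), the interval switches to a seeded
percentile bootstrap of the mean difference with B = 2000 resamples.
Percentile was chosen over BCa because the published description says only
"bootstrap methods"; the coverage test shows ~95% empirical coverage at
n = 200. Fisher's exact test enumerates the full hypergeometric support
with fixed margins and sums probabilities ≤ that of the observed table
(with a 10⁻⁹ relative tolerance against floating-point ties); it matches
an exact-fraction enumeration oracle on every table with total ≤ 30.
Bootstrap-flagged published intervals cannot be recomputed from summary
statistics alone (they need the raw per-eye values) and are therefore not
numeric targets anywhere.

## Synthetic phantoms: what they emulate, and what they don't

All generators are deterministic under a fixed seed, and every ground
truth is produced by construction or brute-force pixel/voxel counting with
no shared code path with the measurement modules.

* **Lesion**: a disk with a random branching polyline tree (5 branches,
  tortuosity 0.12, 3-px width) rasterized at 1 px and dilated. Branches
  start slightly off-center in separate angular sectors so tubes rarely
  overlap, keeping the polyline pixel count an honest centerline-length
  truth (overlap would make the rendered network's true centerline shorter
  than the drawn polylines). Flow levels: vessels 220, lesion interior 60,
  background 10, with multiplicative Gaussian speckle (SD 0.05 of signal)
  clipped at zero.
* **CC slab**: uniform background 180 with deficit disks at 40, speckle as
  above, optional multiplicative shading shared by the flow and structure
  images to exercise compensation. The default deficit set (300 disjoint
  disks, 30–180 µm) covers roughly 8% of the scan — in the range of the
  deficit fractions the biomarker takes on real scans. That coverage
  matters: the mean − 1 SD global threshold assumes deficits contribute
  visibly to the intensity histogram, and a near-deficit-free image would
  place the threshold inside the background mode.
* **PED**: flat BM with anterior Gaussian RPE bumps; per-bump analytic
  volume 2πσ²h (cross-checked in tests by fine-grid numeric integration).
* **Choroid**: bright stroma (200) with dark vessels (50) as x-aligned
  random cylinders, or an exact constructed per-A-scan vessel fraction;
  truth MCT/CVI by voxel counting inside the 5-mm circle.
* **Cohort**: per-metric visit-2 values and monthly rates drawn from the
  configured group moments (defaults emulate the studied cohort of 12
  non-exudating vs 9 exudating eyes), visit-1 back-computed from intervals
  of 3.6 ± 2.1 / 2.7 ± 1.7 months (clipped at 0.5 months); a
  lognormal-shifted option produces skewed metrics for exercising the
  normality gate.

The phantoms omit real OCT speckle statistics (spatially correlated,
signal-dependent), the optical PSF, motion artifacts, curved anatomy, and
clinically realistic vessel density (phantom VAD ≈ 0.08–0.17 versus ~0.4–0.5
in the studied lesions, because sparse trees are required for an unambiguous
centerline truth). Passing recovery tests therefore demonstrates
correctness of the measurement arithmetic and the robustness of each
operator to small-grain noise at the stated levels — not end-to-end
accuracy on clinical images.

## Problem sizes in the test suite

Image tests run on the native 6 × 6-mm grid at 12-µm pitch (500 × 500);
3-D choroid phantoms use a 6 × 6-mm grid at 24-µm lateral / 8-µm axial
sampling (250 × 250 × ~45), which keeps volumes small while leaving the
5-mm circle uncut. Recovery properties use 20 seeds (5 for the 3-D
choroid), and bootstrap coverage uses 500 replications at n = 200 per
group, B = 2000.

## Known limitations

* The lesion and vessel detectors are transparent re-implementations of
  algorithms whose exact published operators are proprietary or
  under-specified; agreement is demonstrated on phantoms only.
* The per-image mean − kSD deficit threshold is sensitive to the deficit
  fraction itself at very low coverage; normative fixed-threshold mode
  avoids this when an instrument constant is available.
* Visit-pair selection assumes one eligible exudation date per eye and
  numeric study days; calendar handling is left to the caller.
* Bootstrap-flagged published intervals are not reproducible from summary
  statistics and are out of numeric scope.
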