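# Methods

## Imaging model and what the generator emulates

The synthetic angiogram reproduces the acquisition geometry of plasma-
labeled two-photon stacks: a 3D volume imaged one z-plane at a time at
1 frame/s with 1 μm axial spacing (defaults; both configurable). Each
z-plane is a snapshot at its own acquisition time. Because a capillary's
tube spans several planes, the same in-plane stretch of lumen is imaged
several times, seconds apart — this is the physical basis of stall
scoring from a single stack, and the generator makes it explicit.

Vessels are random piecewise-smooth 3D polylines with circular cross-
section, gently curved and kept shallow in z so that most of a segment is
visible in each plane it crosses. Diameters are drawn uniformly from the
capillary range (default 3–9 μm). Lumens render bright
(`contrast` × background); RBCs render as dark super-Gaussian shadows
whose darkening depends only on arclength along the centerline, assigned
from the in-plane nearest centerline point — so a stalled vessel's shadow
pattern is *identical* in every plane it crosses (frame-to-frame lumen
correlation exactly 1 in the noise-free limit). Flowing vessels follow a
renewal process: cells advance by `v·Δt` between frames, exit downstream
and fresh cells enter upstream as a Poisson stream, so each frame shows a
stationary single-file configuration with no wrap-around aliasing.

Deliberate simplifications, and hence what passing tests do *not* show
about real data:

* No optical point-spread function, depth attenuation, or motion
  artifacts; noise is shot (Poisson, `photon_scale` photons per intensity
  unit, default 10) plus Gaussian read noise (default sd 2 on a
  background of 20 and lumen of 80).
* The rendered shadow half-length is the lumen-filling ellipsoid of
  45 μm³ capped at 3 μm (in the narrowest capillaries an elongated cell's
  tapering ends still transmit); real shadows in 3 μm vessels can be
  longer, which would make classical segmentation harder than it is here.
* Vessels are junction-free open tubes with ≥ 6.5 μm clearance between
  lumen surfaces; real cortical networks branch and touch, which is why
  the original workflow used a learned segmenter.
* Flux and speed are coupled through a linear cell density clipped to
  0.05–0.15 cells/μm (the single-file physiological band); flux draws
  outside that band are projected back onto it.

The generator declares a stall/flow separation margin of 0.15: on
noise-free stacks at default conditions every flowing segment's motion
statistic exceeds every stalled segment's by at least the margin (design
measurements across 80 seeds: stalled ≤ 0.12, flowing ≥ 0.30). A segment
whose lumen shows no cell shadow in any frame carries no evidence either
way and is reported unscorable rather than guessed.

## Stall scoring

The motion statistic is `1 − mean frame-to-frame Pearson correlation` of
lumen intensity sampled at the segment's in-plane centerline positions,
over consecutive planes that share at least 5 samples. Samples are taken
half a voxel inside the lumen so static boundary/background structure
cannot inflate the correlation. Pairs whose difference is below 2% of the
intensity scale count as unchanged (correlation 1) — a real shadow
darkens the lumen by tens of percent, and at default noise the photon
noise alone exceeds this threshold, so the rule only absorbs sampling
artifacts; pairs where a shadow appears or vanishes outright count as
full motion; featureless-bright pairs are skipped.

Simulated annotators vote per segment (default 20 votes) as Bernoulli
draws at their sensitivity (stalled truth) or specificity (flowing
truth). Crowd confidence is the sensitivity-weighted fraction of
"stalled" votes; this weighting is this package's own pooling rule,
isolated behind one function so alternatives (log-odds, specificity-
aware) can be swapped. Triage validates records with confidence ≥ 0.5
(inclusive) in strictly descending order and auto-labels the rest
flowing; unscorable segments are excluded from both numerator and
denominator of stall density.

## Segmentation and geometry

The segmenter is a classical stand-in with the same output contract as a
learned one (a boolean mask congruent with the stack):

1. Gaussian smoothing (σ = 0.5 voxel) and a **half-maximum threshold**
   midway between the background level (volume median) and the lumen
   brightness (99.5th percentile). Unlike Otsu, this keeps a blurred
   tube's boundary at its true radius; with a small bright foreground
   Otsu under-thresholds and inflates thin tubes by 1–2 voxels.
2. Morphological closing (ball radius 1) and **shadow-gap bridging**:
   cell shadows are nearly as dark as background and cut each lumen into
   fragments, so nearby mask components are reconnected when the straight
   path between their closest voxels stays above a shadow-level
   (liberal) intensity threshold — background never does — painting a
   cylinder at the local tube radius. Components smaller than 64 voxels
   are removed.
3. `invert=True` handles inverted-contrast data; a stack without
   vessel-like signal (foreground less than 3 background sd above the
   background mean) yields an empty mask and a warning, not an error.

Centerlines come from 3D skeletonization; skeleton voxels with ≠ 2
neighbors (26-connectivity) are nodes, adjacent node voxels merge into
one junction, and degree-2 chains are traced into edges. Two artifact
repairs follow, both at the scale of one tube diameter (10 voxels): leaf
spurs shorter than that are pruned, and short junction-junction edges
(small skeleton cycles at bulges) are contracted; degree-2 merges then
restore single junction-to-junction paths.

Per segment: length is the summed inter-voxel step length in μm after a
5-point moving-average smoothing of the path (a raw one-voxel skeleton
staircases and inflates curved-vessel length by ~5%; endpoints are
pinned); the chord is the endpoint distance; tortuosity their ratio
(floored at 1); diameter is twice the mean Euclidean distance transform
(anisotropic sampling in μm) along the path. Edges shorter than 3 voxels
or with a degenerate chord are dropped and logged. The capillary filter
keeps diameter ≤ 10 μm — the boundary value is retained — and is
idempotent and monotone in the threshold.

Recovery is assessed on the *interior* of each true centerline, trimmed
by one tube radius plus one shadow length (5 μm) at both ends: skeletons
retract at open tube ends, and a cell shadow sitting at a vessel end
occludes it entirely in the rendered data, so the end caps are not
recoverable from the image by any segmenter. On default 25-vessel
volumes ≥ 90% of true segments are matched within a 2-voxel one-sided
Hausdorff distance.

## Velocimetry

Speed: the record is split into 40-ms windows (the highest-energy
windows are used, at most 6, so sparse records are estimated where the
streaks are); per window, the streak angle maximizes the variance of
binned Radon projections of the mean-subtracted window over a 1° grid on
(−89°, 89°), refined by bounded scalar minimization, then polished by a
sub-pixel shear alignment (steep slopes, > 1 px/line, are refined on the
transposed image in 1/d where the shear stays in bounds). Window speeds
`|tan θ|·pixel_size·line_rate` are aggregated by quality-filtered median;
shallow-angle (slow-flow) results are re-estimated on 5× longer windows
where the slope is better conditioned. Direction is discarded. A flat
image raises a "no flow signal" error; angles at the grid boundary warn
of aliasing. Units are μm and seconds internally; speeds are reported in
mm/s.

Flux: the intensity time series at the scan center (3-column average) is
matched-filtered at the expected shadow transit width; dips are counted
with a minimum separation of a quarter transit. `single_file` is false
when crossings are closer than one shadow transit, or when crossing
times at two separated columns are inconsistent with a single common
speed (a second file at a different speed breaks the constant lag each
RBC must show between columns). Two cells arriving within a small
fraction of a transit form one visual streak and are counted once.

Hematocrit: `Hct = f·V_RBC/(v·π·R²)` with v converted to μm/s and
V_RBC = 45 μm³; v = 0 returns NaN with a warning (undefined for a
stalled vessel), never infinity. Note f and v are physically coupled
(f = density·v); the "Hct < 1" sanity property holds over jointly
physiological (density, v, R) draws, not over independent f and v
extremes.

## Statistics

* `compare_groups`: Shapiro-Wilk on each group (gate α = 0.05, same as
  the test α by default); both normal → unpaired equal-variance t-test,
  else two-sided Mann-Whitney (exact for small samples without ties via
  scipy's method selection). The result carries the gate p-values, the
  mean difference with a 95% t-interval, and the minimum detectable mean
  shift at the realized pooled sd. Monte-Carlo operating characteristic:
  type-I error 0.05 ± 0.015 at n = 4 per group.
* `nested_anova`: hierarchical sums of squares with units (mice) nested
  in groups; the group F uses the unit-within-group mean square as its
  error term (`F = MS_group / MS_unit(group)`, df `g−1, M−g`), never the
  per-vessel residual. Balanced case reduces to the t-test on unit means
  (F = t²). Groups need ≥ 2 units; all-equal data returns F = 0, p = 1.
* `pearson_correlation`: product-moment r, R², two-sided p, least-squares
  line; zero-variance input is an error.
* Power inversions: the minimum detectable proportion difference inverts
  an unpooled two-proportion z power function (both rejection tails, so
  power → α as the difference → 0) by monotone root search; direction
  "increase"/"decrease"/"any" (a decrease is detectable at a smaller
  difference because binomial variance shrinks with p). The minimum
  detectable mean shift inverts the noncentral-t power of the two-sample
  t-test (statsmodels) and scales by sd; optionally also returned as a
  percent of a reference mean. Both match Monte-Carlo power within
  simulation error. "Power = 0.80" is the detection probability (the
  conventional 1 − β), configurable.
* Behavior: preference = t_replaced/(t_replaced + t_other) (0.5 is
  chance); spontaneous alternation = triads/(entries − 2) with the
  maximum-triads bound enforced and fewer than 3 entries undefined
  (NaN). No multiple-testing correction is applied by default, matching
  per-test reporting.

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale sizes chosen as
defaults: 25-vessel 150×150×60 μm stacks for image-based checks;
~2,000-segment geometry-only simulations (the vote pipeline never reads
pixels, so rendering is skipped there) for stall-fraction recovery at
stall fractions 0.005–0.05 across 20 seeds; 50 noisy line scans per speed
in {0.1, 0.5, 1, 2, 5, 10} mm/s; 1,000 null seeds for the gated test and
500 for the nested ANOVA; 20,000-replicate vectorized Monte-Carlo for
power checks. All randomness flows from explicit integer seeds;
identical seeds give bit-identical stacks, line scans and vote tables.

Known limitations: flux counting undercounts when the configured flux
approaches the single-file resolution limit (crossings merge); the
classical segmenter needs the declared inter-vessel clearance and would
fragment on touching vessels; the motion statistic needs a segment
visible in at least two planes with shared samples, and reports NaN
otherwise; the nested ANOVA implements one grouping factor with units
nested in it (a diameter covariate can be added upstream of it by
residualizing, but is not built in).
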