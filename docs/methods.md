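# Methods

## Problem and scope

`choroquant` quantifies the vascular status of the choroid — the vascular
layer between retina and sclera — from radial swept-source OCT (SS-OCT)
B-scan sets. The readout is the choroidal vascularity index

CVI = LV / TCV,

the luminal (vessel) volume over the total choroidal volume, together with
LV, SV (stroma) and TCV in mm³ over the standard macular regions (0–3, 3–6
and 0–6 mm diameter rings centered on the fovea). On OCT, vessel interiors
are hyporeflective and the stromal connective tissue is hyperreflective, so
lumen and stroma can be separated by local intensity thresholding.

The package also implements the downstream statistics of a paired
physiological-challenge design: every subject is measured under a control
and an acute-hyperglycemia (75 g oral glucose) condition at five timepoints
(ambient-light baseline, after 45 min dark adaptation, and 30 s / 2 min /
5 min after return to ambient light), and condition contrasts are estimated
per timepoint with covariate adjustment for axial length and age.

No clinical images ship with the package. All image-level validation runs on
a synthetic phantom generator with exact ground truth; all statistics-level
validation runs on a simulated cohort. What that does and does not establish
is discussed at the end.

## Scan model

A session is `n_radials` B-scans acquired as spokes through the fovea at
`angle_step_deg` increments; the invariant `n_radials × angle_step_deg =
180°` expresses that the spokes tile the half-circle (each line contributes
two opposite semi-meridians). The defaults mirror the clinical acquisition
protocol: 18 radials at 10°, 12 mm scan width, 2048 A-lines, 3 mm axial
depth; the phantom rasterizes 512 axial pixels. Row 0 is the vitreous side;
pixel intervals are half-open `[i, i+1)`. The fovea is a single shared
column index supplied as input (it is marked manually in practice; radial
scans intersect there by construction).

Sessions round-trip losslessly through a directory of 8/16-bit grayscale
TIFF/PNG files plus a JSON sidecar (`session.json`) naming the geometry,
subject covariates, condition/timepoint label, fovea column and bit depth.

## Segmentation and flattening

The retinal pigment epithelium (RPE) is found as the minimum-cost
left-to-right path through the negated axially Gaussian-smoothed image —
i.e. the brightest continuous band — under a ±2 px/column slope constraint
(dynamic programming; ties break toward the smaller row). Flattening shifts
each column by an integer so the RPE lands on its median row; shifts are
integer on purpose, so the per-column intensity multiset feeding the
thresholding stage is untouched. Columns that would lose more than half
their extent are an error.

The choroid's upper boundary is taken as the bottom edge of the RPE band
(whether the clinical upper boundary is Bruch's membrane or the RPE inner
edge is genuinely ambiguous; this choice is flagged, not asserted).  Both
choroidal boundaries are minimum-cost paths through a gradient cost image:
the forward axial difference of the 3×3-median-despeckled scan, box-smoothed
3 px axially and 31 columns laterally. The lateral smoothing matters: the
RPE bottom edge and the choroid–sclera interface are laterally coherent
across the whole scan, while vessel-lumen edges inside the choroid are not;
without it the lower-boundary path measurably locks onto vessel edges
(≈8 px bias at the default geometry). The lower boundary additionally
carries a region term, +0.5 × the mean brightness of the next 10 rows:
vessels clipped at the band bottom imitate bright→dark edges a few rows
above the true interface, but only the interface has genuinely dark sclera
below it. Pixels vacated by flattening (zero-filled) are replaced by a
low-percentile background estimate before the costs are formed so they
create neither spurious edges nor artificially dark regions. Axial box
smoothing turns a sharp edge between rows b−1 and b into a two-row cost
plateau; with the smallest-row tie-break the path settles on b−2, so the
upper boundary is reported as `path + 2`, which is exact on noiseless
edges; for the lower boundary the region term strictly decreases across
the plateau, the path lands on b−1, and the boundary is `path + 1`. The lower boundary is
constrained at least 5 px (`min_thickness_px`) below the upper one to stop
the path collapsing onto the RPE under noise; as a consequence the detector
never reports a zero-thickness choroid (degenerate coincident boundaries
are supported through `use_external_boundaries`, which also serves users
who bring boundaries from their own — e.g. learned — segmenter).

## Binarization

Niblack's local threshold: `T(x) = m(x) + k·s(x)` with `m`, `s` the mean and
population standard deviation over a square window centered on `x`, clipped
at the image borders (statistics over in-image pixels only — no padding).
Defaults follow the settings conventionally used for choroid binarization:
31×31 window (`window_radius_px = 15`), `k = −0.2`. Pixels with intensity
≤ T are lumen (ties to lumen, fixed for oracle testing); the ROI between the
choroid boundaries is partitioned exactly. The implementation uses integral
images; on integer-valued images the windowed sums are exact in float64, so
the threshold map is bit-identical to a naive per-pixel loop with the same
`sqrt(E[x²]−E[x]²)` formula — that equivalence is enforced in the tests.

Two defaults deserve justification:

* **Despeckle.** A 3×3 median precedes thresholding (the classical CVI
  workflow's despeckle step). Under the phantom's i.i.d. multiplicative
  speckle at 4 looks, raw Niblack misclassifies tens of percent of pixels in
  locally homogeneous windows — the threshold sits a fixed 0.2 local-sd
  below the local mean, so in pure-noise windows ≈42% of pixels fall below
  it regardless of noise level. Median despeckling shrinks the noise while
  preserving vessel edges.
* **ROI-restricted window statistics** (`roi_only=True`). With whole-image
  windows, pixels near the lower choroid boundary mix the dark sclera into
  `m`, dragging the threshold below the lumen level and erasing lumen along
  the bottom of the band (≈−0.04 CVI bias at default conditions).
  Restricting the statistics to ROI pixels removes that edge artifact.
  Whole-image statistics remain available (`roi_only=False`).

## Quantification

Each semi-meridian represents an angular sector of width Δθ = π/n_radials.
A column at fundus radius r contributes `h · r · Δr · Δθ` per compartment,
with `h` its compartment thickness (pixel count × axial mm/px) and
Δr the lateral pixel pitch; summing columns and semi-meridians integrates
volume in polar coordinates and converges to `π(R_out² − R_in²)·t` for a
constant-thickness band (≤1% discretization error at the default geometry —
enforced by test). Each column's full thickness is assigned to the ring
containing its center radius (half-open in radius; no partial-area
weighting); the fovea column carries zero weight (r = 0). Ring extents are
diameters, following the macular-grid convention.

Ocular magnification is corrected laterally with Bennett's formula,
`q(AL) = 0.01306·(AL − 1.82)` mm/deg, applied as the ratio `q(AL)/q(AL_ref)`
with reference axial length 24.46 mm (emmetropic), so the device constant
cancels; the axial scale is unaffected. A session's CVI is the ratio of
summed volumes; cohort statistics average per-subject CVIs (mean of
ratios) — on the reference cohort's printed means the two conventions
differ by ~0.05 percentage points (58.82 vs 58.77%).

## Phantom generator

Per B-scan, the phantom stacks: background (level 30), a retina band with a
Gaussian foveal dip, an RPE band 3–5 px thick (level 230), and a choroid
band (stroma level 160) whose position and thickness undulate as
band-limited cosine curves (amplitude 0.05 mm, thickness 0.30 mm mean).
Elliptical lumen blobs (level 40) with semi-axes drawn from 3–9 px
(laterally; 0.6× axially — vessel cross-sections are flattened) are placed
uniformly in the band, overlap allowed and clipped to the band, until the
lumen pixel fraction reaches the target (default 0.59); realized fractions
land within one blob of the target, well inside ±0.03. A per-scan linear
tilt (uniform within ±5°) is applied as integer per-column shifts, and
multiplicative gamma speckle (shape = `speckle_looks`, default 4, unit
mean; ∞ = noiseless) multiplies the level map before quantization to the
declared bit depth. The lumen level sits just above background because
blood is essentially transparent at 1050 nm — vessel interiors on SS-OCT
are close to the noise floor.

Ground truth carries every boundary curve, lumen mask and tilt shift in the
final image frame, plus regional volumes computed by the same polar rule
directly from the truth masks (`truth_volumes`) — the oracle for everything
downstream of binarization.

The cohort-level simulator (`simulate_cohort_table`) operates on session
summary values rather than pixels: per-subject baselines (TCV 26.08 mm³,
CVI 58.77%, between-subject sds converted from the reference cohort's
reported SEs at n = 24) plus session noise scaled so the paired-difference
SEs match the reference contrast table (session sd 0.37 mm³ TCV / 0.22%
CVI gives SE(d) = 2σ/√24 ≈ 0.15 / 0.09). Condition effects are additive
shifts on (TCV, CVI) for the hyperglycemia condition at chosen timepoints;
LV and SV are derived (LV = CVI·TCV, SV = TCV − LV), keeping the identity
LV + SV = TCV exact in simulated tables.

## Adaptation statistics

The estimand at a post-baseline timepoint is the between-condition
difference of within-condition changes from baseline, per subject
(`d_i`). Covariate adjustment is ordinary least squares of `d_i` on
mean-centered axial length and age: for a two-condition within-subject
design, differencing absorbs the subject random intercept exactly, so this
matches the mixed-model estimand while remaining fully specifiable. With no
covariates the estimator *is* the paired t-test (identical statistic, df
and p — tested to 1e-12). Constant or collinear covariates fall back to the
unadjusted test with a warning; all-equal differences report se = 0 with
p = 0 (or 1 when the common value is 0). No multiplicity correction is
applied by default; a Holm step-down over the report grid is available
behind a flag.

A caveat the report makes explicit: all timepoint contrasts share the two
baseline sessions, so their errors are correlated within a cohort — a single
unlucky baseline draw stars several cells at once. Calibration is therefore
judged on replicated null cohorts (the starred-cell rate over 500 seeded
replicates sits in the nominal 3–7% band), not on any single grid.

## Numerical choices

* Dynamic programming tie-breaks: smallest row, both per transition and at
  the final column — segmentation is fully deterministic.
* Flatten shifts, tilt shifts: integers; vacated pixels are zero-filled.
* Thresholding ties (intensity == T) are lumen.
* Volumes: float64 sums over per-column pixel counts; LV + SV = TCV holds to
  ≤1e−9 mm³ and rings are additive to the same tolerance.
* CVI with TCV = 0 is *missing* (NaN), never 0.
* All randomness flows from `numpy.random.default_rng(seed)`; equal seeds
  give bit-identical phantoms, CSVs and reports (output headers carry the
  seed and a config hash instead of timestamps).

## Validation sizes

The CVI-recovery experiment uses 20 phantoms at the full clinical geometry
(18 × 512 × 2048) with target fractions spanning 0.45–0.70 at 4-look
speckle, plus two noiseless phantoms; statistics calibration uses 500 null
cohort replicates and 100 effect replicates at n = 24. These sizes give
sub-percent Monte-Carlo error on the rates being checked while keeping a
full run in minutes on one CPU.

## Limitations

* The phantom's speckle is i.i.d. per pixel; real OCT speckle is spatially
  correlated with the resolution cell and further shaped by frame
  averaging. Accuracy here is reported as a function of contrast and noise,
  not at a hardware-matched operating point.
* Binarization accuracy degrades when vessel lumina are much smaller than
  the despeckle kernel (erosion of capillary-scale blobs) or much larger
  than the Niblack window (homogeneous-window pathology inside large
  lumina); the defaults are tuned to the Sattler/Haller caliber range the
  0–6 mm CVI is dominated by.
* The classical boundary detector replaces the learned segmenter used
  clinically; it assumes a dominant bright RPE band and a clear
  choroid–sclera edge, and does not handle pathology (detachments, drusen).
  External boundary import exists precisely for that case.
* Passing phantom-based tests demonstrates internal consistency of the
  pipeline and correctness of the geometry/statistics, not clinical
  accuracy on real eyes.
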