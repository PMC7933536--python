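# Methods

## Problem and measurement model

`tilquant` quantifies tumour-infiltrating lymphocytes (TILs) around a manually
outlined invasive tumour ("bulk") on a co-registered slide pair, and estimates
the prognostic value of the resulting densities. Inputs per case are: the bulk
outline as polygons in micrometre slide coordinates, an epithelium/stroma label
raster covering the bulk's bounding box at a stated resolution, per-marker
(CD3, CD8, FOXP3) point detections, and relapse-free / overall survival
records (months + event indicator).

Seven measurement regions are derived per tumour:

| region | definition |
|---|---|
| ITA | the whole bulk (intratumoural area) |
| ITT | epithelial pixels of the bulk |
| ITS | stromal pixels of the bulk |
| IM1 | band of ±500 µm around the bulk outline (total width 1 mm) |
| IM2 | band of ±1 mm around the bulk outline (total width 2 mm) |
| IM1IO, IM2IO | ratio of TIL density in the inner (tumour-side) to the outer half of the band |

Bands are built by polygon offsetting with round joins (Minkowski sum /
difference with a disk), so band membership is exactly Euclidean
distance-to-outline ≤ half-width; the test suite checks this equivalence
against a brute-force distance oracle on a 5 µm grid. Multi-focal bulks are
offset per component and unioned (overlap counted once). The outer half is
clipped to the tissue extent and the clipped area is used in densities, so
tumours abutting the section edge do not get artificially deflated outer
densities. If the erosion annihilates the bulk (tumour thinner than twice the
half-width) the inner half is the whole bulk and the result is flagged rather
than rejected.

Coordinate conventions (used everywhere): micrometres, origin top-left,
y increasing downward; even-odd polygon fill; rasters sampled at pixel
centres, 0-based indices, half-open pixel extents.

### Areas and the partition identity

The ITA area is defined on the raster — the number of pixels whose centre
falls inside the bulk times the pixel area — rather than as the polygon area.
This makes the partition identity `area(ITA) = area(ITT) + area(ITS)` exact on
every case (the exact polygon area is also carried; the two differ by at most
a boundary-quantisation term of order perimeter × pixel size). Bulk pixels the
upstream segmenter left unlabelled inherit the nearest labelled pixel's class
via a Euclidean distance transform.

### Counting and tie rules

A detection exactly on the bulk outline counts on the tumour side. Inside the
bulk a detection takes the class of the pixel containing it (after the
nearest-label fill), so `count(ITA) = count(ITT) + count(ITS)` holds exactly.
Any fixed rule preserves conservation; this one is cheap and deterministic.

### Measures

Densities are counts per mm² of region area. Survival covariates are the
density per increment of 100 cells (CD3, CD8) or 10 cells (FOXP3, reflecting
its sparsity). Between-marker ratios (CD8/CD3, FOXP3/CD3, CD8/FOXP3) use
absolute counts within a region; the inner/outer versions are the cross-ratio
of the two markers' IO ratios. Zero denominators make a measure undefined
(NaN) for that case — never 0 or infinity — and undefined cases are excluded
from that measure's downstream model with a logged exclusion count. Values are
carried at full floating precision; rounding happens only at report time.

Density heatmaps use a circular sliding window of 1 mm² (radius
√(1/π) mm ≈ 564.19 µm) on a 250 µm grid (visualisation granularity only);
windows overhanging the frame are normalised by the clipped disk area.

## Survival analysis

Each measure is a continuous covariate in a univariable Cox proportional-
hazards model. Choices where the convention was genuinely open:

* **Ties:** Efron approximation — standard and more accurate than Breslow
  under the month-resolution ties registry data produce.
* **CI:** percentile bootstrap of exp(β̂) over patient resamples with
  replacement, 5000 resamples by default, seeded; non-converged resamples are
  dropped and counted.
* **p-value:** full-sample Wald test (not bootstrap-based).
* **No multiplicity correction** is applied to the estimates; results with
  p < 0.05 are annotated with whether they would survive a Bonferroni
  correction across the 7 measures of that marker (or marker pair) and
  outcome.

The single-covariate partial-likelihood solver is implemented in vectorised
numpy (Newton with step-halving, |β| capped at 50 as a monotone-likelihood
guard) because a 5000-resample bootstrap over ~90 measure/outcome fits needs
per-fit cost in the tens of microseconds; it is cross-checked against
lifelines' `CoxPHFitter` (agreement to ~1e-4, limited by lifelines' own
convergence tolerance) and against the closed-form two-group exponential
estimator at large n. Zero covariate variance or fewer than two events yields
`converged=False` with a diagnostic, not an exception; an all-censored outcome
is rejected.

For intratumoural measures the cohort is also dichotomized at the sample
median (values equal to the median go to the low group; `numpy.median`
interpolated cutoff — the grouping is identical under the lower-interpolation
median) and compared with Kaplan–Meier curves and a two-sample log-rank test
(lifelines). The log-rank statistic equals the Cox score test at β = 0, which
the suite verifies, alongside a hand-tabulated 6-patient example.

Cohort characteristic tables report count and percent of cohort to one
decimal with half-up rounding.

## Synthetic cohort

No imaging cohort is distributed, so a generator emulates all four inputs
with the statistical structure the measures assume. Defaults (chosen once, as
study conditions):

* **Geometry:** radial-Fourier-perturbed disks, R ~ N(2.0, 0.4) mm (floored
  at 0.8 mm), 4 harmonics with 1/k-damped amplitudes (log-sd 0.08);
  non-simple draws are resampled. Tissue frame: bounding box + 3 mm.
* **Mask:** Gaussian-smoothed white noise (150 µm smoothing) thresholded at
  the in-bulk quantile matching an epithelial fraction of 0.55, rasterised at
  20 µm/px. This is far coarser than the 0.12 µm/px native scan resolution
  (exported as a constant for real-data manifests): compartment structure at
  the ~100 µm scale is what the measures integrate over, and desk-scale
  rasters keep a 94-case cohort in seconds. The geometry code accepts any
  resolution.
* **Infiltrates:** inhomogeneous Poisson by thinning a homogeneous proposal
  at the intensity ceiling. Base intensities (cells/mm², epithelium / stroma /
  outside): CD3 150/400/150, CD8 60/160/60, FOXP3 15/40/15 — stroma-dominant
  infiltration with CD8 a subset of CD3 and FOXP3 an order of magnitude
  sparser, the regime motivating its smaller covariate increment. Three
  phenotypes span the behaviours the IO ratios detect: `inflamed` (as
  configured), `excluded` (intratumoural intensity × exp(−d/τ), τ = 300 µm,
  d = depth from the outline), `desert` (zero inside the bulk). A mean-one
  lognormal per-case factor (log-sd 0.6) scales all intensities, giving the
  marked hot/cold between-tumour heterogeneity real cohorts show; without it
  every survival covariate would be nearly degenerate.
* **Outcomes:** death times from a Weibull baseline (shape 1.5, scale 120
  months) with hazard multiplied by exp(β·z), z the centred prognostic
  covariate (default CD3_ITA, β = log 0.85 per unit for both outcomes);
  uniform administrative censoring whose horizon is found by bisection on the
  realised sample to hit a 33% death rate; a latent recurrence process (same
  β, scale calibrated the same way to a 23% relapse rate) defines relapse
  events, so RFS time ≤ OS time always. Target event rates mirror a ~94
  patient triple-negative breast cancer discovery cohort.

Everything is reproducible bit-for-bit from `(config, seed)`;
per-case streams come from `SeedSequence([seed, case_index])`.

**What the generator does not emulate** — and hence what green tests do not
show about real data: staining/unmixing noise and detection errors,
registration distortion between stain and H&E coordinates (only a global
affine is supported), necrosis and fat within the bulk, non-proportional
hazards, informative censoring, and competing risks. Passing tests establish
that the geometry, counting and inference machinery is correct under the
stated model, not that TIL densities are prognostic in any particular cohort.

## Numerical choices and problem sizes

Buffers use 32 segments per quarter circle (offset error ≪ 1 µm at these
widths). The distance-oracle agreement threshold is 99.5% at 5 µm grid pitch
with disagreements confined to one pitch of the band edge. Calibration suites
run at deliberately modest sizes — 50 cohorts of n = 300 with 500 bootstrap
resamples for hazard-ratio recovery and CI coverage, 1000 small-cohort
replicates for the type-I error of the Wald test, 200 tumours for the
homogeneous inner/outer-ratio check — chosen so the whole suite runs in about
a minute while keeping Monte-Carlo error well inside the asserted bands;
5000 remains the default bootstrap count for analyses.

## Known limitations

* Only univariable models; no stratification, PH diagnostics or competing
  risks.
* The affine transform slot is the only registration facility; nonlinear
  co-registration must happen upstream.
* The compartment model is strictly two-class inside the bulk; a third class
  from an upstream segmenter must be merged by the caller.
* Percentile bootstrap CIs can be erratic when a measure is nearly degenerate
  (e.g. count ratios with tiny variance); such fits are reported as computed,
  with convergence flags, rather than special-cased.
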