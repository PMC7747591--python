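# Methods

## The measurement model

Magnetization transfer (MT) imaging compares two co-acquired axial images of
the cervical cord at each intervertebral level (C2/3–C5/6): `I_o` without and
`I_MT` with an off-resonance saturation pulse. Saturating the
macromolecule-bound proton pool attenuates tissue signal in proportion to its
macromolecular (largely myelin) content, so the magnetization transfer ratio

    MTR = (I_o − I_MT) / I_o × 100%

is a per-pixel percent saturation: high in myelinated white matter (WM,
roughly 38–43% at 3 T), lower in grey matter (GM), near zero in CSF.

Per-tract MTR values are read out over eight WM tracts (bilateral lateral
corticospinal tracts CST, cuneate fasciculi CF, gracile fasciculi GF, and
combined spinothalamic + spinoreticular tracts SPTH). The homogeneity index
over the tract vector x (N = 8) is

    MTRh = sqrt(N/(N−1)) · sqrt( Σ(x − x̄)² / Σx² )

— a scaled standard deviation normalized by the root sum of squares, i.e. the
fractional-anisotropy formula applied to tract values. Properties (all
tested): MTRh(c·x) = MTRh(x) for c > 0, so participant- and coil-dependent
signal scale cancels; MTRh = 0 iff all tracts agree; 0 ≤ MTRh ≤ 1 for
nonnegative x with the maximum attained by a single nonzero entry; and
depressing one tract further below the group mean — the focal-demyelination
signature the index targets — can only increase it. The unrestricted
"farther from the mean" direction is *not* monotone: raising an above-mean
value also inflates the Σx² normalization and can marginally lower the index
(~7% of random perturbations). By convention MTRh of an all-zero vector is 0.

Slices are analyzed independently per level; the standard analysis requires
all 8 tracts (N = 8 fixed). A relaxed policy recomputes MTRh with N equal to
the available tract count when at least 6 are present; every record stores
which extraction method and tract count produced it.

## Phantom

The generator emulates the data-generating structure of an axial cord MT
acquisition, with known ground truth at every stage.

**Geometry.** 128×128 grid at 0.5 mm in-plane (the acquisition's nominal
resolution); elliptical cord with semi-axes 6.5 mm (left–right) × 4.25 mm
(anterior–posterior), matching a mid-cervical cord cross-section; butterfly
GM built from two horn ellipses plus a central commissure; a 2.5 mm CSF ring
so segmentation faces a realistic bright boundary. The eight tracts are
angular sectors of the WM (gracile medial-dorsal, cuneate lateral-dorsal,
corticospinal dorsolateral, spinothalamic/spinoreticular anterolateral),
mirror-paired exactly about the midline because the grid center falls between
pixels. Sector shapes are free parameters of the package, not anatomical
claims. With `soften_sigma > 0` the compartment one-hot maps are Gaussian
smoothed into a probabilistic atlas whose per-pixel fractions sum to 1,
producing controlled partial-volume mixing at every boundary.

**Signal.** MT-off intensities: WM 100, GM 115, CSF 200 (arbitrary units;
CSF brightest as on the T2\*-weighted acquisition). MT-on obeys
`I_MT = I_o · (1 − MTR/100)` per compartment, mixed linearly by the
partial-volume fractions. Default tissue MTR: per-tract WM baselines
39.5–40.5% (CST 39.5, CF 39.8, SPTH 40.2, GF 40.5 — values chosen on the
38–43% scale reported for healthy cervical WM), GM 32%, CSF 2%. A Gaussian
point-spread blur (`psf_sigma_px`, default 0.7 px) models the band-limited
acquisition; arithmetic exactness tests switch it off. Noise is Rician
(magnitude of a complex Gaussian, scale `noise_sigma`); `noise_sigma = 5`
with WM at 100 gives SNR 20, the condition used throughout the noisy tests.
In background air the magnitude reduces to a Rayleigh distribution (verified
by Kolmogorov–Smirnov on 10⁴ pixels).

**Misalignment and lesions.** Inter-scan motion is a rigid in-plane offset
applied to `I_o` only (the registration target frame is `I_MT`), bounded at
10 voxels / 10°; cohort simulation draws it per slice with SD 1 voxel and
1.5°. A lesion drops the MTR of chosen tracts by `mtr_reduction` percentage
points over a contiguous blob covering an `extent` fraction of the tract
area, grown around the tract centroid. Ground truth records the
area-weighted true MTR per tract, so a full-extent lesion shifts truth by
exactly the reduction.

**Cohorts.** Default cell sizes follow the study structure: recovered
17F/13M, mild 28F/4M, severe 11F/3M (76 subjects; 57/88/79% female). Year-1
NDI% is drawn per group from a normal truncated to the group's
classification band (recovered < 10, mild 10–28, severe > 28; means/SDs
5.53/6.40, 19.2/10.2, 29.7/13.6), so drawn labels equal intended cells and
power experiments keep exact cell sizes; `truncate_ndi=False` draws
untruncated values, labels subjects by the drawn NDI and warns about drift.
Age and BMI come from per-group normals (means 31.7/35.9/36.1 years,
23.9/24.2/26.7 kg/m²). The lesion lands in the severe-female cell by
default. A lightweight companion (`simulate_metric_table`) draws
subject×level metric tables directly — cell mean + subject random intercept
+ level noise — for statistical calibration studies that do not need images.

**What the phantom does not emulate.** Pulse-sequence physics, B0/B1
inhomogeneity, through-slice effects, anatomical variation between subjects
(one atlas serves the whole cohort), cord curvature, flow/motion artifacts,
and the intensity nonuniformities that make real cord segmentation hard.
Passing tests therefore demonstrate correctness of the pipeline's
computations and calibration of its statistics under the stated noise model
— not robustness to real-world acquisition pathology.

## Registration

Cord masks come from intensity alone: a three-class multi-Otsu threshold
(air / cord parenchyma / CSF), largest 4-connected middle-class component,
morphological closing and hole filling. A mask whose area falls outside
25–400% of the expected cord area (π·6.5·4.25 ≈ 87 mm², configurable)
rejects the slice rather than raising.

`I_o` → `I_MT` registration is two-stage, as in the study: translation
initialization from the cord-mask centers of mass, then maximization of
normalized cross-correlation inside a circular mask of diameter 35 voxels
centered on the `I_MT` cord centroid (the mask restricts the cost only, not
the overlap domain). The search is a coarse grid over rotation ±10° in 0.5°
steps with a ±2-voxel translation grid per angle, followed by Nelder–Mead
refinement of (tx, ty, θ). Coordinates are 0-based (row, col); rotation is
about the `I_MT` cord centroid with positive θ rotating the +row axis toward
+col.

Numerical choices that mattered:

- **Interpolation.** The coarse grid scores with bilinear interpolation
  (speed); the refinement and all reported NCC values use cubic splines.
  Bilinear scoring alone biased the rotation estimate by 0.3–0.8° — the
  interpolation smoothing penalty competes with the alignment gain — and
  cubic refinement removes that bias at ~2× cost. The final resample is
  bilinear.
- **Initial simplex.** Nelder–Mead's default perturbation of a zero
  coordinate is ~2.5e-4, which strands θ at a 0° start; the refinement seeds
  an explicit simplex with 0.5-voxel / 0.5° edges.
- **Cropping.** Cost evaluation runs on the cost-mask bounding box plus a
  search margin, ~7× faster than the full frame with identical results.
- **Guarantee.** The returned transform's NCC never falls below the
  center-of-mass initialization; if refinement cannot beat it, the
  initialization is returned flagged `com_only`. Slices with final NCC
  below 0.5 are rejected downstream — the automated stand-in for the
  study's visual quality review.

Measured on the phantom: noiseless recovery of |t| ≤ 5 voxel, |θ| ≤ 5°
misalignments is accurate to ≲0.12° and ≲0.02 voxel; at SNR 20 the
0.5-voxel/0.5° recovery rate over 50 replicates is 100%.

## Tract extraction

`mask_mean` is the probability-weighted mean of valid MTR pixels per tract.
`map` jointly estimates the 8 tract values plus nuisance compartments by
penalized least squares on the partial-volume model `pixel ≈ Σ_A p_A·μ_A`:
the design holds the tract probability maps, a residual-WM column, the GM
mask, and an edge column (exponential decay of the distance to the cord
boundary, length scale 1.5 px) that absorbs CSF partial-volume
contamination. A Gaussian prior `μ_A ~ N(WM grand mean, prior_sd²)` with
`prior_sd = 5` percentage points enters as a ridge penalty weighted by
σ̂²/prior_sd², σ̂² being the residual variance of the unpenalized fit — so a
noiseless well-posed slice is reproduced exactly (the penalty vanishes)
while noisy fits shrink toward the WM mean.

Two further choices control edge bias. Pixels with `I_o ≤ 1e-6 × max(I_o)`
are marked invalid rather than zero (division guard), and the extraction
domain is eroded 1 px in from the cord boundary: rim pixels mix bright CSF
into the ratio with double weight (CSF is both low-MTR and high-intensity)
and bias every tract low by several percentage points otherwise. Negative
MTR pixels are kept — clipping would bias tract means — and surface in QC.
Tracts with fewer than 3 effective pixels yield a flagged missing value.

On the probabilistic atlas at SNR 20 (50 replicates) the MAP estimator's
tract RMSE is ≈2.3 percentage points versus ≈5.3 for mask means; residual
error is dominated by boundary partial volume, which affects all subjects
identically and therefore cancels in group contrasts.

## Statistics

Stage 1 runs a one-way ANOVA on clinical outcome for each metric (8 tract
MTRs and MTRh, averaged per subject over available levels — the
subject-level aggregation is implied by the between-groups degrees of
freedom in this design). Stage 2, triggered per metric by stage-1
significance (gating is on by default and configurable), refits with outcome
and sex crossed, using Type III sums of squares with sum-coded factors on
the unbalanced design. Both stages use α = 0.05 and Bonferroni-adjusted
pairwise post-hoc contrasts with a pooled error term.

Stage 3 fits a linear mixed model on the slice-level long table (tract-level
for MTR, adding tract and side factors): fixed effects outcome, sex,
outcome×sex, BMI, age, level; random intercept per subject. Least-square
means evaluate the fixed-effect design per outcome×sex cell at covariate
means, averaging over levels (and tract/side); contrasts cover
within-sex-across-status and between-sex-within-status comparisons with Wald
p-values, and the interaction is tested by a Wald chi-square on its
coefficient block. A singular or non-converging fit falls back to OLS on the
same fixed effects, flagged `ols_fallback` (this also makes noiseless
recovery exact). Boundary NDI values 10 and 28 classify as mild (closed
reading of the 10–28 band); out-of-range NDI raises.

Quality-rejected slices leave missing values that are multiply imputed
(5 sets): within each outcome×sex cell, a linear regression of the observed
values on age, BMI and level indicators (cells with fewer than 8 observed
rows borrow the global fit; a cell more than 50% missing is refused),
filling each gap with the prediction plus a residual resampled with
replacement. Per-set LS-means and contrasts are pooled by Rubin's rules;
the pooled interaction chi-square uses a simple mean-statistic combination,
an approximation noted in the result flags.

Calibration measured at the study cell sizes: interaction type-I error
0.034–0.060 across 500-replicate batches (binomial SE ≈ 0.01); power for a
severe-female MTRh elevation of 2.5 within-subject SDs ≈ 1.0 over 100
replicates.

## Problem sizes

Simulation studies in the test-suite and acceptance script use: 50
registration replicates at SNR 20; 50 extraction replicates; 500 null
replicates for type-I calibration; 100 replicates for power; a 12-subject,
2-level demo cohort for the end-to-end determinism check. These sizes give
binomial/Monte-Carlo standard errors comfortably inside the asserted margins
while keeping a full run under a few minutes on one core.

## Known limitations

- One shared atlas stands in for per-subject anatomy, so atlas-to-image
  registration reduces to the rigid chain; the nonlinear template warping a
  real study needs is out of scope.
- Tract MTR absolute accuracy is limited by boundary partial volume
  (systematic ≈1–2 pp after mitigation); group contrasts are unaffected.
- The mixed model's LS-mean confidence intervals are Wald (normal)
  intervals; with very small cells (e.g. 3 severe males) they are
  approximate.
- The pooled interaction test across imputations is a mean-chi-square
  approximation rather than a full D1/D2 combination.
- Segmentation is a three-class intensity model adequate for phantoms; it is
  not a substitute for anatomical segmentation of real cord images.
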