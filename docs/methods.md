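# Methods

## The measurement model

An en-face choriocapillaris (CC) slab is a square grayscale raster with a
physical pixel pitch (6000 µm / image width; 5.86 µm at the native
1024 px).  Two slab conventions are carried as metadata: 10 µm thick
starting 31 µm below the RPE-fit reference, and 20 µm thick starting 29 µm
below it.  All intensities are normalized to [0, 1] by the source dtype's
full range — never by the per-image maximum, which would make thresholds
non-portable across scans.

### Compensation

Flow signal under an attenuating RPE/drusen complex is dimmed in both the
angiographic and the structural slab.  Compensation divides the angio
image by the structural image after Gaussian smoothing (σ in µm, converted
through the pitch), max-normalization to (0, 1] and clamping below at a
floor:

    compensated = clip( angio / max(smooth(structural)/max, floor), 0, 1 )

Defaults: σ = 5 µm, floor = 0.05, both config keys.  The σ default is
deliberately close to the native pitch: the structural dip caused by a
large choroidal vessel (LCV) spans only a few tens of µm, and a kernel
much wider than the vessel caliber cannot track it — division then leaves
a dark reconstruction ring around every vessel instead of cancelling the
shared suppression.  A small σ makes the correction effectively pixelwise
while still damping detector noise at native resolution.  The floor
prevents unbounded amplification where the structural signal is nearly
absent.  This operation is an attenuation-correction in the division
style; it is configurable and is not claimed to reproduce any specific
published implementation's internal arithmetic.  Under a flat structural
field it is exactly the identity, which is pinned by tests.

### Binarization

The Phansalkar local threshold over a digital-disk window (pixel included
iff its center distance ≤ radius, mirror-padded at borders):

    t = μ · (1 + p·exp(−q·μ) + k·(σ/r − 1)),   k=0.25, r=0.5, p=2, q=10

σ is the population (divide-by-N) standard deviation; whether historical
Fiji builds used N or N−1 in the window is not decidable from published
descriptions, so the population choice is pinned by a regression test, not
claimed.  A pixel at or below its threshold is a flow-deficit (FD) pixel;
ties go to deficit, so degenerate all-zero images are classified rather
than rejected.  Window sums are accumulated in row-major offset order,
which makes the map reproducible bit-for-bit against a scalar double-loop
reference.  Two radii matter: the conventional 15 px preset and
`round(ICD/pitch)` — 4 px at 1024 px / 6 mm for the 24 µm intercapillary
distance (ICD).

### Particle analysis and sectors

FD components are 8-connected (diagonal contact joins, as in ImageJ's
particle analyzer; pinned by a diagonal-pair test).  Components smaller
than the area of a circle with the ICD as diameter,
`ceil(π(ICD/2)²/pitch²)` = 14 px at native pitch, are removed (strict <,
mirroring "smaller than").  The published rule conflates a length (24 µm)
with an area; the circle-equivalent reading is adopted and both the ICD
and the rule are configurable.

FD% is measured in four 1×1 mm squares flush to the image corners, side
`round(1000/pitch)` px (171 at native pitch).  Fundus-display orientation
is assumed: nasal is the right image half in OD, mirrored in OS, and
configurable for other device dialects.  Sector indices 1–4 are
temporal-superior, nasal-superior, nasal-inferior, temporal-inferior; the
vertical position is recorded but not modelled.  Excluded pixels (dilated
superficial-plexus masks) count neither in the FD numerator nor the
denominator; a sector with zero valid pixels is an error, not a zero.

### Choroidal thickness

CT is the axial gap between the outer Bruch's-membrane border and the
inner scleral border, sampled at the sub-foveal center (cCT) and the four
sector centers.  An optional tilt correction multiplies by cos of the
local BM inclination (plane fit over a 5 px radius); it is off by default
because at macular tilt angles (≲10°, cos ≥ 0.985) the correction is
smaller than manual-caliper noise.  Real-data workflows can supply
precomputed CT values as CSV instead of surfaces.

## Statistical layer

One eye per patient, so eye = cluster = patient everywhere.

* **FD% mixed model.**  REML linear mixed model with random intercept per
  eye; fixed effects LCV + group + orientation + LCV×group (the two other
  pairwise interactions are omitted — the two-step refit drops them when
  their F-test p > 0.05, and the shipped model is the post-drop form).
  Four planned contrasts (LCV within iAMD, LCV within control, group
  within LCV = 0, group within LCV = 1) with Bonferroni ×4: adjusted
  p = min(1, 4p) and 98.75% CIs.  Drusen-flagged sectors are excluded here
  (drusen corrupt the FD measurement) but retained in all LCV-visibility
  models.
* **Sector-level LCV visibility.**  Logistic regression with a Gaussian
  random intercept per eye, fitted by maximum likelihood with 25-point
  Gauss–Hermite quadrature.  Estimation is deterministic: start at the
  plain-logistic solution, L-BFGS-B with the random-effect SD bounded at
  zero, Wald SEs from the numerical Hessian (at the σ = 0 boundary the
  fixed-effect block reduces to ordinary logistic regression).  The fit
  agrees with lme4's `glmer` (nAGQ = 25) to ~1e-4 on shared datasets,
  which a test enforces.  Separation is reported as a flag, never a crash.
  Univariate models per predictor; predictors with univariate p < 0.05
  enter the multivariable model together with the CT×orientation
  interaction.
* **Eye-level visibility.**  Ordinary logistic regression of "LCV in at
  least one sector" on cCT, eye color or spherical equivalent (no random
  effect needed at one row per eye).
* **Youden cutoff.**  Candidate thresholds are midpoints between adjacent
  distinct CT values; a sector is called LCV-positive iff CT ≤ threshold
  (the ≤ convention matches how such cutoffs are reported); J = sens +
  spec − 1 is maximized with ties broken toward the smallest threshold.
  Sensitivity/specificity 95% CIs use the closed-form cluster ratio
  estimator: p̂ = Σxᵢ/Σnᵢ, var = m/((m−1)(Σnᵢ)²)·Σ(xᵢ−p̂nᵢ)², Wald
  interval clipped to [0, 1].  With independent Bernoulli sectors it
  reproduces the ordinary binomial Wald interval (checked by simulation).

## The synthetic cohort

The generator emulates the statistical structure the analyses assume, not
OCT physics.  Per eye, in one authoritative draw order shared by the image
renderer and a fast truth-only path:

* cCT ~ N(197, 82²) µm; sector CT ~ sector-specific normal laws (means
  194/148/121/157 µm, SD 63 µm — nasal sectors thinner), coupled to cCT
  with correlation 0.85 and truncated at 30 µm;
* LCV visibility per sector ~ Bernoulli(logistic(α + γ·CT + δ·nasal + u)),
  γ = ln 0.94 per µm, δ = ln 6.23, u ~ N(0, 2²) per eye, α = 5.30; the
  intercept, coupling and random-effect SD were calibrated once so that
  ≈26% of sectors and ≈55% of eyes carry LCV;
* true FD fraction per sector ~ N(9%, 2²%) in iAMD and N(6%, 2²%) in
  controls (clipped to [0, 0.5]); the levels are calibration constants —
  only their ordering is a claim;
* drusen count ~ Poisson(0.4) per eye, placed in random sectors (≈47
  affected squares per 118 eyes);
* metadata: eye color (30/29/41% brown/green/blue), |spherical
  equivalent| ~ |N(1.6, 1.15²)| dpt.

Rendering: flow texture is white noise smoothed at 18 µm and
rank-normalized; the darkest per-sector quantile at the drawn FD fraction
becomes the deficit set (exact by construction), mapped to a dark band
(0.04–0.14) while flow occupies a bright band (0.67–0.82 after slab
brightness).  The bands are deliberately separated so that the Phansalkar
threshold falls into the gap — this is what makes measured FD% track the
true fraction (Pearson ≈ 0.99 over 60 eyes) and is the generator's
central calibration.  Drusen are Gaussian attenuation disks applied to
*both* images; superficial vessels are Bézier streaks recorded in the
exclusion mask; LCV are 2–4 Bézier tubes per affected sector (widths
50–150 µm, config range) whose footprint *replaces* the texture in both
images with 20% of the local flow/structural level, feathered over 20 µm.
Because the suppression is shared between slabs, compensation cancels it
and the deficits hidden beneath the tube stay hidden — measured FD% drops
in LCV sectors, which is the masking mechanism under study.  The tube
geometry draws are consumed from the random stream whether or not LCV are
rendered, so with/without renders pair exactly.

Limitations relative to real data: no speckle statistics, no motion or
projection-removal artifacts, no drusen elevation geometry, no 3-D
attenuation, binary LCV appearance without caliber–contrast coupling.
Passing tests therefore demonstrate the correctness of the measurement
and inference chain under a controlled generative law — not device-level
realism.

## Problem sizes and numerical choices

Cohort-level image checks run at 256 px (pitch 23.4 µm), where the
per-eye pipeline costs ~0.4 s; geometry arithmetic is always asserted at
the native 1024 px.  Parameter-recovery studies use 200 replicates of
118-eye cohorts at the truth-table level (the generative laws for CT and
LCV need no rendering).  The Youden recovery study centers the CT
distribution on the crossing point of its logistic law, where prevalence
is ½ and the Youden optimum coincides with that crossing; with an
off-center CT distribution the optimum shifts toward the prevalence odds,
which is a property of the index, not an estimator defect.  All model
fits are deterministic given the input table; there are no stochastic
optimizers anywhere in the inference path.

Degenerate inputs are classified, not errored, wherever a classification
is well defined (all-zero images are all-FD; empty masks give empty
component lists); errors are reserved for genuinely undefined quantities
(FD% of a fully excluded sector, CT at an inverted boundary, single-class
outcomes).
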