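# Methods

`ceusvv` quantifies adventitial vasa-vasorum (VV) perfusion from
contrast-enhanced ultrasound (CEUS) cine loops and validates the whole
chain — imaging model, ROI quantification, and group statistics — on a
synthetic cohort whose ground truth is known exactly. This note records
the models, the conventions, the calibration choices, and what the
synthetic validation does and does not demonstrate.

## Imaging model

**Replenishment kinetics.** After a destruction pulse clears microbubbles
from the imaging plane, video-intensity in a perfused compartment recovers
as the standard mono-exponential destruction–replenishment curve

    I(t) = I0 + A · (1 − exp(−β (t − t0))),   t ≥ t0,

with baseline `I0`, plateau enhancement `A` (proportional to fractional
vascular volume), rate `β` (1/s, proportional to flow), and pulse time
`t0`; intensity holds at `I0` before the pulse. CEUS acquisitions are
sometimes bolus wash-in rather than post-destruction replenishment; the
curve shape is the same family and `t0` is exposed so either reading can
be emulated. All intensities live on a linear 8-bit video scale (0–255);
no log/dB compression is modelled.

**Phantom.** The 2-D long-axis vessel is idealized as horizontal bands: a
luminal band flanked by two adventitial bands, everything else background
tissue at a constant level, with an optional plaque polygon carved out of
the lumen (small and distal for the small-plaque group, filling most of
the distal lumen for the occlusive group). Each compartment's pixels
follow its replenishment curve exactly; additive Gaussian noise (default
sd 4 intensity units) is applied per pixel and frame, then clipped to
[0, 255]. Multiplicative speckle is deliberately not modelled: the
quantification averages over ROIs of hundreds of pixels, so only the mean
and variance of the noise reach the statistic under test. Frames are
sampled at `floor(duration · frame_rate) + 1` time points `k / frame_rate`
(defaults 5 fps for 30 s, pulse at 2 s).

## ROI quantification

**Rasterization.** Pixels are 0-based, row-major; pixel (i, j) spans
[j, j+1) × [i, i+1) and belongs to an ROI iff its center (j+0.5, i+0.5)
is inside the polygon under the even–odd rule. Boundary centers are
resolved by a half-open crossing convention (an edge counts when
`(y1 ≤ y) != (y2 ≤ y)` and the center is strictly left of the
intersection), which is deterministic and makes polygons sharing an edge
partition pixels exactly. Polygon simplicity is validated with shapely;
the rasterizer itself is implemented directly because its edge convention
is part of the package contract.

**TIC, background, MVE.** The time–intensity curve (TIC) is the
arithmetic per-frame mean over the mask. Background is the mean TIC value
over frames strictly before the destruction pulse (an explicit `[start,
end)` window can override; without any pulse marker, onset is detected as
the first frame exceeding the curve minimum by 10% of its range — a
heuristic that can fold the earliest sub-threshold rise into the
reference, which is why the pulse time should be supplied when known).
MVE is the TIC maximum minus background; ties take the earliest frame; a
negative MVE (background above every frame) is reported with a warning
rather than clamped so the statistic's distribution is not truncated.
Optional smoothing is a centered moving average with edge truncation,
off by default and recorded in the curve metadata.

**Normalization.** Normalized MVE divides the adventitial MVE by the MVE
of a luminal reference ROI drawn proximal to the lesion. Both terms are
background-subtracted by default — normalizing raw maxima would leave the
ratio dependent on tissue baseline — but a `raw-max` variant is available
for sensitivity analysis. The subtracted ratio is invariant under a global
affine gain applied to both TICs with backgrounds recomputed. The
occlusive-plaque group (group 5) has no enhanceable luminal reference; it
is simulated and counted for histology but its normalized MVE is never
computed, and the cohort table enforces that invariant.

## Cohort generator

Six groups emulate graded carotid atherosclerosis: chow-fed control
(group 0), high-fat diet for three durations (1–3), diet plus balloon
endothelial injury producing a small (<50% stenosis) plaque (4), and a
near-occlusive plaque (5). A latent VV density `d_g` drives everything:

- default densities (0.146, 0.278, 0.435, 0.660, 0.660) for groups 0–4
  equal the group-mean enhancement ratios the pipeline should recover;
  with the default unit gain-to-lumen ratio the per-animal true
  normalized MVE *is* the per-animal density, keeping ground truth
  analytically transparent. Group 5's density (1.10) is not constrained
  by any printed ratio; it is set above group 4 so the abrupt histology
  increase of the occlusive stage is reproduced.
- per-animal biological variability is a lognormal multiplier with mean 1
  and sigma 0.5 (coefficient of variation ≈ 53%, the order of the
  group-level CVs such cohorts show); the adventitial amplitude is
  `gain · d_g · L` and the same multiplied density feeds histology.
- two observers independently count microvessels per cross-section as
  Poisson draws with rate `a + b·d`; the analysis uses their mean, so the
  count's conditional variance is `λ/2`.

**Marker calibration.** The count links are anchored at the control
density and the early-atherosclerosis (diet-only) mean density with the
corresponding mean counts (VEGF 1.30 → 3.58, CD31 1.90 → 6.21). The exact
two-point line has a negative intercept for both markers — counts rise
steeper than density near the control — which a Poisson rate cannot have,
so the calibration clamps `a = 0` and takes the least-squares slope
through both anchors (VEGF b ≈ 9.88, CD31 b ≈ 16.79). The fitted rates
sit within ~0.5 counts of both anchors.

Because the linkage is an exact Poisson link to the same latent density
that drives enhancement, the simulated MVE–count correlations (~0.9 at
the default calibration) are *stronger* than the ~0.5–0.65 reported for
real cohorts, where histology sectioning, imaging physics and biological
decoupling add noise the generator does not model. A weaker linkage with
any target correlation can be constructed analytically (see below).

**Determinism.** One cohort seed spawns one child seed per animal
(`numpy` SeedSequence); each animal consumes its draws in a fixed order
(lognormal multiplier, CD31 counts, VEGF counts, imaging noise), so a
config plus seed reproduces the cohort bit-for-bit, and the pipeline's
global seed fans out to stage seeds by hashing the stage name with the
seed. Cohort and ground-truth CSVs are written at full float precision so
a CSV round trip is exact; derived report tables use 9 significant
digits. Two rendering modes exist: `frames` renders every cine loop and
extracts TICs through the measurement ROIs; `tics` synthesizes the
ROI-mean TICs directly with noise sd `noise_sd/√n_pixels`, which is
statistically equivalent up to clipping and far cheaper for replication
studies.

## Statistical layer

All statistics are computed from their defining formulas, with p-values
from `scipy.stats` reference distributions; scipy's own test functions
appear only as independent cross-checks in the test suite. Tests are
two-sided throughout.

- **t test**: Student (pooled variance, df `n_a+n_b−2`, the default) and
  Welch (Satterthwaite df). Raw samples are reduced to (n, mean, sd)
  before computing, so raw and summary inputs are bit-consistent. Zero
  pooled variance degenerates to p = 1 (equal means) or a flagged p = 0.
- **one-way ANOVA**: `F = MS_between/MS_within` with (k−1, N−k) df; a zero
  within mean square yields F = 0, p = 1 when the between mean square is
  also zero, otherwise a flagged infinite F. The phrase "Friedman one-way
  ANOVA" is contradictory for independent groups, so classical ANOVA
  (used by the cohort report) and the Friedman test (for block designs)
  are separate named operations and never substituted for each other.
- **Friedman**: within-block midranks, the standard tie correction
  `1 − Σ(t³−t)/(bk(k²−1))`, chi-square reference with k−1 df; fully tied
  blocks give statistic 0, p = 1. The chi-square reference is asymptotic
  in the number of blocks, noticeably conservative below ~15 blocks; the
  null-calibration study therefore uses 30 blocks.
- **Dunnett T3**: for every pair, `|Δmean| / sqrt(s_i²/n_i + s_j²/n_j)`
  with Welch df, referred to the studentized maximum modulus (SMM)
  distribution with `m = k(k−1)/2` parameters. The SMM survival function
  `P(max|Z_i|/S > q)` (S a shared `χ_ν/√ν`) has no closed form and is
  evaluated by adaptive quadrature of `(2Φ(qs)−1)^m` against the scaled
  chi density, falling back to Monte Carlo at fixed seed 20170801 if the
  quadrature misbehaves; agreement with a 10⁶-draw Monte-Carlo oracle is
  verified to within 0.005. At m = 1 the SMM reduces to the two-sided t
  probability, and the adjusted p always dominates the per-pair Welch p.
  The cohort report runs all pairs and flags control contrasts; no
  additional FDR layer is added.
- **Pearson correlation**: product-moment r with `t = r√((n−2)/(1−r²))`;
  constant input is an error; the classical Fisher z interval is provided
  on the result object.

## Verification studies

The `studies` module re-derives pipeline properties against independent
references; the acceptance tests assert on its outputs and
`scripts/acceptance.py` reports them.

- *Oracle equivalence*: vectorized TIC extraction vs an explicit
  per-pixel double loop on 100 random loops (≤ 32×32×50), tolerance
  1e-12; t/F/r vs plain-loop formula transcriptions on 1000 random small
  samples, tolerance 1e-10.
- *Closed form*: a noiseless loop sampled to 20 s after the pulse, where
  MVE must equal `40(1−e^{−10})` and normalized MVE the amplitude ratio
  0.4, within 1e-6.
- *Parameter recovery*: 50 animals per group, full rendering; each
  group-mean normalized MVE must land within 3 standard errors of its
  configured truth with groups 0–3 strictly ordered. (Group 4 shares
  group 3's truth, so no order is asserted between them.)
- *Correlation recovery*: the linkage intercept is solved analytically so
  the population correlation between true enhancement ratio and observer
  mean count is 0.6 (the closed form uses the lognormal mixture moments
  and `Var(count) = b²Var(D) + E[λ]/2`); 100 replicate cohorts are
  simulated. The primary check is truth-centered: each replicate's Fisher
  z must fall inside the central 95% region around `atanh(0.6)` with the
  sampling SD taken from the replicates — the standard recovery-test
  form, exactly calibrated by construction, and the study also verifies
  the estimator is unbiased on the z scale. Two per-replicate intervals
  (bootstrap-SE on z, classical Fisher) are reported alongside: the
  design mixes five discrete group densities with lognormal and Poisson
  variation, which inflates `Var(z)` above the bivariate-normal `1/(n−3)`,
  so the Fisher interval under-covers here by construction and the
  bootstrap interval sits between the two — the three counts make that
  calibration hierarchy visible rather than hiding it.
- *Null calibration*: 10,000 exchangeable Gaussian nulls per test (two
  groups of 10 for t; five groups of 8 for ANOVA; 30×4 for Friedman);
  rejection rates at α = 0.05 must lie in [0.04, 0.06].
- *Printed-summary check*: the Student t test applied to the published
  total-cholesterol summaries (18.948 ± 4.633 vs 2.901 ± 2.788, n = 10
  per group) must fall below the printed p < 0.001 bound.

Problem sizes (50/group for recovery, 100 replicates, 10,000 nulls,
10⁶ Monte-Carlo draws) are chosen so every study is decisive at its
tolerance while the whole suite runs in well under a minute of
simulation-heavy work.

## What passing does and does not show

The synthetic cohort demonstrates that the *pipeline* is correct: exact
quantification in the noiseless limit, unbiased recovery of group means
and correlations under the modelled noise, and correctly calibrated
statistics. It does not validate the imaging physics of real CEUS
(speckle, attenuation, motion, nonlinear bubble response), automatic ROI
placement (ROIs are always inputs), or the biological claim that
enhancement tracks VV density — the generator assumes that linkage rather
than testing it. Real-data correlations will be weaker than the simulated
ones for the reasons above, and the group-5 density, plaque kinetics
(half the adventitial amplitude at a slower rate) and tissue baselines
are plausible idealizations, not fitted quantities. Attrition is not
simulated; group sizes are configuration.
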