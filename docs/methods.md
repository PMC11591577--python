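# Methods

`ftirchem` implements a complete chemometric discrimination workflow for
fingerprint-region (1500-1000 cm⁻¹) ATR-FTIR spectra of blood, of the kind
used in pilot diagnostic studies of neurodegenerative disease: spectral
conditioning, stepwise-orthogonalization variable selection with linear
discriminant analysis, soft class modelling (SIMCA), latent-variable
discriminant models (PLS-DA / OPLS-DA) with importance scoring, and
single-wavenumber ROC diagnostics. Because clinical spectra of this kind
are rarely deposited, the package ships a synthetic cohort generator with
known ground truth; every statistical claim made by the test suite is a
claim about that generator's output.

## The synthetic cohort

The generator emulates a 76-sample four-group cohort: 19 ALS patients at
diagnosis (`ALS_T0`), 16 after six months (`ALS_T6`), 15 healthy controls
(`HC`) and 7 patients with other neuromuscular disorders (`ON`). A
spectrum is built as

1. a serum-like base profile — ten Gaussian bands (CH₂/CH₃ bending,
   amide III, phosphate and carbohydrate stretches) with per-subject
   amplitude variability (`band_cv`, default 4%);
2. marker metabolite bands at 1335.5, 1304, 1449.5 (and 1393.5) cm⁻¹:
   each exists in every subject at a baseline amplitude (0.10 AU) with a
   small per-subject spread, and its group mean is shifted by the planted
   effect (e.g. −0.0124 AU at 1335.5 cm⁻¹ for `ALS_T0`). Marker bands are
   narrow (σ = 1.5 cm⁻¹) relative to the base bands;
3. two latent "metabolic axis" factors — per-subject standard-normal
   scores with fixed loadings across the three markers. They give the
   marker bands the correlated within-class covariance of a co-regulated
   metabolite panel. This matters: with purely independent noise the
   between-class signal of a two-group cohort is rank one, and stepwise
   decorrelation necessarily destroys every redundant marker after the
   first pick (the residual selection weight is capped at the noise
   floor). Shared covariance is what makes stepwise decorrelation
   productive on real spectra, and the generator reproduces it. The
   loading patterns are chosen orthogonal to the class-difference pattern;
4. instrument artifacts per replicate acquisition — multiplicative scatter
   (uniform 0.95-1.05), linear baseline (offset ±0.02 AU, slope
   ±2·10⁻⁵ AU/cm⁻¹), additive white noise (0.004 AU per point). Three
   replicates are averaged per sample, mirroring triplicate ATR practice;
   the per-scan averaging inside an acquisition is folded into the noise
   standard deviation.

Default marker shifts put the standardized between-group difference at the
marker columns at roughly 1.8-2.3 within-class standard deviations after
preprocessing — the regime in which a single band's AUROC falls in the
0.70-0.97 range typical of published blood-spectroscopy pilots.
`marker_recovery_config()` provides a two-class (19/15) variant with 1.5×
stronger shifts (≈3 sd) used when the property under test is *recovery of
every planted band* rather than diagnostic realism.

What the generator does **not** emulate: water-vapour and CO₂ lines, ATR
penetration-depth dispersion, detector drift across a measurement session,
batch effects, or any biological heterogeneity beyond the Gaussian factor
model. A green test suite therefore says the algorithms behave correctly
on data with this covariance structure, not that the clinical separations
would replicate.

## Preprocessing

Order: crop to the closed interval [1000, 1500] cm⁻¹ → per-spectrum
normalization (unit Euclidean norm by default; SNV available) → 5-point
moving average (edges shrink symmetrically) → 11-point Savitzky-Golay
second derivative, polynomial order 3, divided by the squared grid step so
values are in AU·cm² and independent of the data interval. The derivative
uses one-sided polynomial fits at the edges. Band maxima appear as
negative minima in the second derivative; the normalization removes
multiplicative scatter (noise-free rows `r` and `c·r` give identical
output) and the derivative annihilates linear baselines on the interior.

Autoscaling (mean 0, sd 1 per column, n−1 denominator) is deliberately not
part of this chain: it is fitted on training data inside each model and
applied unchanged to test data, so no test sample ever influences a fitted
parameter. Zero-variance columns get sd 1 with a warning.

The polynomial order (3), moving-average window (5) and normalization
flavour (vector norm) are conventional defaults, all exposed in
`PreprocessConfig`.

## SELECT stepwise orthogonalization + LDA

Selection weight: the Fisher ratio, between-class variance (G−1
denominator) over pooled within-class variance (n−G denominator), which for
two balanced classes ranks variables identically to squared point-biserial
correlation. Each round picks the argmax (ties to the lower column index),
then projects every remaining column onto the orthogonal complement of the
pick, so redundant neighbours of a chosen band are never co-selected. The
retained count is bounded by the 3:1 samples-to-variables rule
(`floor(n/3)`); the pipeline caps a larger request at the bound.
Variables separating classes with zero within-class variance get a large
sentinel weight (1e12); a zero-norm best column stops selection early with
a warning.

LDA is fitted on the original autoscaled values of the selected
wavenumbers (not the decorrelated residuals), so the model applies
directly to new spectra; pooled within-class covariance, equal priors,
assignment by minimal Mahalanobis distance with ties to the first label.
Canonical variates (generalized eigenvectors of the between/within pair)
are exported for score plots. A degenerate covariance gets a ridge of
1e−8·trace/p (1e−10 if the trace is zero), logged as a warning.

Three validation figures are reported, mirroring standard discriminant
tables: resubstitution ("Classification"), leave-one-out CV on the fixed
selected subset ("Prediction"), and a stratified held-out external test
("External Prediction"); the total rate is the sample-weighted mean of the
per-class rates, i.e. plain accuracy. **The fixed-subset LOO figure is
optimistically biased** whenever the subset was selected on all training
samples — on null cohorts it reads near 100%. `nested_loo_select_lda`
re-runs autoscaling and selection inside every fold and is the honest
estimate of the whole procedure's accuracy; under a null cohort it sits at
chance.

## SIMCA

Per-class PCA on class-centered data. Component count per class is chosen
by leave-one-out PRESS, capped at 3 (an override is provided). Residual
conventions: per-variable residual sd uses n−A−1 degrees of freedom; the
pooled class dispersion s₀ additionally divides by the residual
dimensionality p−A, so with A = 0 everything collapses to the pooled sd
about the centroid. An object's distance is its residual root-mean-square
over the p−A residual dimensions; membership is tested by
F = s²/s₀² against the classic SIMCA critical value with
(p−A, (n−A−1)(p−A)) degrees of freedom — other df dialects exist; this one
is used throughout. Open classification may accept an object into
several classes or none; forced classification assigns argmin F/F_crit
(ties to the first model). The F approximation is known to be slightly
conservative for new objects at small n; at n = 50 the measured in-class
acceptance at α = 0.05 is ≈ 0.93.

Modelling power MP = 1 − sd_resid/sd_raw (clipped to [0, 1]; NaN with a
warning for zero-variance variables). Discriminant power
DP = √[(S²(A→B) + S²(B→A)) / (S²(A→A) + S²(B→B))], cross-class
dispersions with an n denominator, own-class with n−A−1; DP ≈ 1 means
non-discriminant, and a zero denominator yields a sentinel. "Efficiency"
is reported as the geometric mean of the class model's open sensitivity
and specificity, "Efficiency Forced Model" the same for forced
assignments — the terms are used inconsistently in the literature and this
definition is fixed here. The internal-prediction column refits the
left-out object's own class model per LOO round with the component count
held fixed.

## PLS-DA / OPLS-DA

Classes are dummy-coded one column per class (also for two classes, for
symmetric reporting); columns are centered. Latent variables are extracted
by NIPALS with deflation of both blocks; R2Y is the explained dummy
variance. Prediction assigns the argmax dummy estimate. OPLS-DA (two
classes, internally a ±1 response) peels `n_orth` class-orthogonal
components from X — weights built from the part of the X-loading
orthogonal to the predictive weight — before extracting a single
predictive component; with no structured orthogonal variation it reduces
to one-component PLS.

VIP_j = √(p·Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a); mean VIP² = 1
identically. On a 0.5 cm⁻¹ grid the VIP spectrum of one absorption band is
a plateau of near-equal columns, so a raw top-10 of columns lists one band
ten times; `top_bands` therefore reports the ten highest *distinct band
maxima* (greedy peak-picking with a 4 cm⁻¹ minimum separation, one
optical-resolution element) — the way important wavenumbers are quoted in
vibrational spectroscopy. The same 4 cm⁻¹ radius is used when matching
bands across strategy lists (consensus) and against planted markers.

Q2Y uses stratified, seeded 5-fold CV with a full refit — including the
autoscaler — per fold: Q2Y = 1 − PRESS/SS over held-out dummy predictions.
The permutation test (default 99 permutations in the pipeline, 999 for
one-off analyses) recomputes R2Y and 5-fold Q2Y under label permutation;
p = (1 + #{perm ≥ observed})/(1 + n_perm), with Q2Y as the primary
statistic. CV-ANOVA is implemented in its simple cross-validated-residual
F form: F = [(SS−PRESS)/d₁]/[PRESS/d₂] with d₁ = number of latent
variables and d₂ = n − d₁ − 1; the result is labelled approximate, and
PRESS ≥ SS reports F ≤ 0 with p = 1.

## ROC diagnostics

Cut points are midpoints of adjacent sorted unique values padded with ±∞;
AUC is the rank-based Mann-Whitney estimate with ties counted one half.
The p-value uses exact U enumeration when n₁·n₂ ≤ 400 and there are no
ties, otherwise the tie-corrected normal approximation (no continuity
correction). The decision direction is explicit ("positive if ≤ cut" or
"≥ cut"); when unset it is auto-chosen as the orientation with AUC ≥ 0.5 —
for second-derivative inputs the positive-if-low rule is the usual
outcome, since band maxima are negative minima. The Youden-optimal cut
maximizes sensitivity + specificity − 1, ties resolved toward higher
sensitivity and then the lower cut value.

## Pipeline

Two default comparisons mirror the published study design: `ALS_T0` vs
`HC` (external test 5+5, OPLS-DA with one orthogonal component) and
`ALS_T0` vs `ALS_T6` vs `ON` (external test 2 per class, two-component
PLS-DA). Per comparison: stratified split → preprocessing (per-spectrum,
split-independent) → train-fitted autoscaler → PCA overview → SELECT-LDA →
SIMCA on the selected variables → latent-variable model with VIP, Q2Y,
permutation and CV-ANOVA → consensus bands (SELECT list ∩ top-10 VIP
bands, 4 cm⁻¹ matching) → ROC per consensus band. All randomness derives
from one root seed through named SHA-256 substreams, so a re-run with the
same config and seed writes byte-identical tables; the output directory is
excluded from the config hash for the same reason.

PCA outlier flags are advisory only (no automatic removal). The stated
confidence level is family-wise — Šidák-shared across samples and the
T²/Q statistic pair — so a clean cohort shows no flag with approximately
that probability; per-sample 99% limits would flag ≈1 of 57 clean samples
in most runs.

## Known limitations

- Single-column identity of a selected variable is ambiguous by
  construction: after an 11-point second-derivative filter on a 0.5 cm⁻¹
  grid, adjacent columns carry near-identical signal but substantially
  independent noise (the filter kernel's lag-1 autocorrelation is ≈0.55),
  so the selection argmax wanders within a band. All band-identity claims
  in this package are made at the ±4 cm⁻¹ (one resolution element) level.
- Fixed-subset LOO after whole-set selection is optimistic (see above);
  the honest nested variant is provided and used for null calibration.
  Note that even nested leave-one-out accuracy is over-dispersed relative
  to a binomial draw under the null (folds share training data), so
  single-cohort chance bands built from the binomial are left by ~15-20%
  of null runs, essentially always on the low side.
- External test sets of 5-10 samples give very coarse external rates
  (steps of 10-20 percentage points); occasional unlucky splits of the
  default cohort select spurious variables and score near chance
  externally, which is a faithful property of the small-n design.
- The SIMCA F limits, CV-ANOVA degrees of freedom and "efficiency"
  definitions follow one specific dialect each, documented above.
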