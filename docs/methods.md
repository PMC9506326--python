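# Methods

## Physical model and assumptions

The package implements the two-component (fat / fat-free) densitometric
model: body density DB (g/mL) determines fat percent through the Brozek
conversion `BF% = 100·(4.57/DB − 4.142)`, which assumes fixed component
densities. DB itself comes from Archimedean weighing at residual lung
volume: body volume is the water mass displaced (mass in air minus
apparent mass in water, over water density) minus the residual lung
volume RV and a fixed 0.1 L gastrointestinal gas allowance.

For weighing with the head above the surface, the head's displaced
volume is missing. Two corrections are provided:

* **HAW(HV)** — a per-sex linear prediction of head volume from head
  girth, face girth and body mass is added back inside the density
  formula. When the predicted head volume equals the Archimedean head
  volume `(MW_HAW − MW_HBW)/DW`, this formula reduces *algebraically*
  to the full-submersion formula; the identity is enforced to 1e−12
  relative in tests and is the backbone correctness check of the
  equation chain.
* **HAW(UD)** — the density formula is evaluated with the
  head-above-water weight as-is ("uncorrected density", biased high
  because the head's volume is omitted) and mapped through a per-sex
  affine regression to criterion density.

Assumptions inherited from the measurement model: the subject holds the
same lung volume in both phases of a trial; RV is adequately predicted
from stature and age (Quanjer; a measured RV can be supplied instead);
water is pure (Kell 1975 polynomial, which matches standard handbook
tables to 1e−5 g/mL on 0–40 °C — dissolved solids in a real pool would
raise DW slightly).

## Trace processing and quality control

Weighing trials are continuously sampled signals (default 40 Hz) with a
head-above plateau and a head-below plateau. Per phase, the recorded
weight is the mean of the contiguous 100-sample window with the
smallest sample SD (n−1 convention; ties broken by earliest start). The
rolling search is O(n) via centered cumulative sums and is tested
against an exhaustive oracle.

Automatic phase segmentation (standing in for the human cursor
operator, which remains available as pass-through manual cursors)
thresholds a 25-sample edge-padded rolling mean at the midpoint of its
5th/95th percentiles and takes the longest run on each side; a minimum
plateau separation of 0.5 kg guards against thresholding noise.

Session QC mirrors the protocol's exclusion rules: at least 3 trials
per phase; no pair of a phase's trial means differing by more than
0.5 kg (strict inequality — exactly 0.5 kg passes); a stable weight of
3 s per phase, interpreted as: the selected 2.5 s window, extended to
3 s within its phase, keeps its SD below 2× the window SD
(configurable). Session weights are the arithmetic means of per-trial
phase means — the homogeneity rule makes fancier weighting pointless.
Repeated head measurements consolidate as: two values < 0.5 cm apart →
their mean; a third measurement agreeing with either earlier one is
recorded; three mutually discordant values signal a full re-measure.

## Derivation and validation statistics

Head-volume equations are derived per sex by exhaustive best-subset OLS
over eight candidate terms (both girths, three diameters, body mass,
and raw squares of the girths), capped at 3 terms to match the
published equation size (cap configurable), selected by smallest SEE.
Two SEE conventions are always reported side by side: derivation SEE
`sqrt(RSS/(n−k−1))`, and validation SEE from regressing the criterion
on the frozen prediction, `sqrt(RSS/(n−2))` (the body-composition
cross-validation convention), alongside the plain RMSE — a constant
prediction offset vanishes from the regression SEE but appears fully in
the RMSE. Raw (uncentered) squares are used because the shipped
equations use raw predictors; the near-collinearity of X and X² over
the narrow observed ranges is tolerated, and only hard rank deficiency
errors (with the implicated columns named via pivoted QR).

The agreement suite uses the difference convention predicted − criterion
throughout. Lin's CCC uses the original n-denominator moments
(the n−1 variant differs in the third decimal at n ≈ 20 and is not
offered); Cb = CCC/ρ; McBride category edges are inclusive on the lower
side (exactly 0.90 and 0.95 → moderate, exactly 0.99 → substantial).
Bland–Altman limits are bias ± 1.96·SD (n−1), with proportional bias as
the plain OLS slope of difference on pairwise mean and its two-sided
t-test. TOST declares equivalence iff the 90 % CI of the paired
difference lies strictly inside the bounds (±0.2 L for head volume,
±2 BF percentage points); its p-value is the larger of the two
one-sided p-values. TOST power is computed exactly as the joint
probability that both one-sided tests reject, by quadrature of the
normal CDF over the chi distribution of the sample SD (4001-point
midpoint rule; agrees with 200k-replicate Monte Carlo within 0.01).
Post hoc power and the minimum n for 0.80 power (linear search from
n = 3) use the observed mean difference and SD as the truth by default;
a flag substitutes a zero true difference.

## Synthetic cohort generator

The generator emulates the study's structure so every stage is testable
without subject data. Anthropometrics follow a single-factor Gaussian
model: one latent standard normal per subject drives the displaced head
mass and, through the published per-variable correlations, every
predictor; marginal means, SDs and admissible ranges default to the
published derivation- and validation-group summaries (head diameters
reuse derivation moments for validation groups, where they were not
taken). Criterion density is drawn independently from the published
group moments (an optional hook induces a density–mass correlation);
immersed weights are then *solved exactly* from the density formula, so
the noiseless pipeline reproduces the drawn density and fat percent to
1e−10. Weighing trials are rendered as 4 s plateau / 1 s transition /
4 s plateau / 1 s surfacing traces with phase-specific Gaussian sample
noise (defaults 0.311/0.396 kg male and 0.223/0.300 kg female for the
above/below phases) and a 0.05 kg per-trial wobble of the plateau
means, sized to exercise — but only rarely trip — the 0.5 kg QC rule.

Head volume is generated in one of two modes. The default `"equation"`
mode sets the true head volume to the shipped prediction equation
evaluated on the drawn predictors plus Gaussian noise (default SD
0.25 L), so the generator owns true coefficients and derivation code
can be tested for parameter recovery. The `"factor"` mode instead takes
the latent displaced mass itself as truth, faithful to the published
marginal structure. The factor model implies corr(Vi, Vj) = ri·rj
between predictors — the full predictor covariance is unknowable from
group summaries, and this is stated openly as the modelling assumption.
Range truncation by rejection sampling (whole-subject redraw, at most
100 attempts) shifts means toward the truncated-normal expectation and
attenuates correlations where the published ranges are asymmetric;
tests therefore compare against accept-reject oracles rather than the
nominal calibration.

What the generator does **not** emulate: breathing and movement
artifacts beyond white noise, practice effects across trials,
inter-predictor correlation structure beyond the single factor, and any
density–anthropometry dependence (unless injected). Passing tests on
synthetic cohorts therefore demonstrate the correctness of the
estimation machinery under the stated model, not the field validity of
the prediction equations.

Water temperature defaults to 35 °C (a typical heated weighing pool);
reports carry the temperature as required metadata rather than assuming
it silently. Reproducibility: one root seed spawns per-subject child
RNG streams, so enlarging a cohort never reshuffles earlier subjects,
and cohorts, traces and reports are pure functions of (config, seed).

## Numerical choices and degenerate inputs

* All operations return unrounded values; rounding (densities 4 dp,
  volumes/BF%/correlations 2 dp) happens only in report formatting.
* Negative fat percent (density above the lean limit 4.57/4.142 g/mL)
  is returned unmodified with a warning flag; clipping would distort
  group statistics.
* Measurements outside the observed calibration ranges warn
  (plausibility flags), never error; physically impossible inputs
  (non-positive denominators, head immersion that fails to reduce
  weight, stature passed in cm to the meters-based RV equation) raise.
* A zero-SD difference vector makes the TOST CI collapse to the mean:
  the decision is still taken (strict containment of the point) and the
  result is flagged degenerate.
* Rolling-window variances are computed on mean-centered samples to
  keep the cumulative sums well conditioned around tens of kg; window
  ties within 1e−9 relative variance resolve to the earliest start.

## Problem sizes

Test and acceptance runs use study-sized cohorts (44/46 derivation,
21/24 validation) for end-to-end checks, 500-subject cohorts × 20 seed
replicates for coefficient recovery, 12 000 subjects for marginal
calibration, 200 000 Monte Carlo replicates for the TOST power oracle,
and 1 000 × n = 500 samples for the Shapiro–Wilk type-I calibration.
At study-sized validation groups the ±0.2 L head-volume bound is tight
relative to the 0.25 L default prediction noise, so a single synthetic
study demonstrates head-volume equivalence only ~80 % of the time;
equivalence checks therefore aggregate over replicate studies.

## Known limitations

* The shipped equations were derived in adults aged 18–36; the
  plausibility ranges encode that population, and extrapolation warns.
* Only the Brozek fat-percent conversion is provided (no Siri or
  population-specific variants, no multi-component models).
* The automatic trace segmentation is a convenience for clean
  two-plateau signals; noisy field recordings should use manual
  cursors.
* Validation-group calibrations reproduce published summary moments,
  not subject-level data, so subject-level quantities (e.g. exact SEEs
  and CCCs of a given real cohort) are not reproducible — only their
  sampling behaviour under the stated model.
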