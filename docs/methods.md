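# Methods

## Scoring model

The three scores summarise stone complexity from non-contrast CT. SHA.LIN
and S.T.O.N.E. are additive band-lookup scores: each raw measurement is
mapped to an integer point value by a fixed band table and the points are
summed. Guy's grade is not additive; it is the first matching rule in an
ordered precedence list (complete staghorn or a neurological condition →
IV; partial staghorn/diverticulum stone or multiple stones with abnormal
anatomy → III; solitary upper-calyx stone, multiple stones with normal
anatomy, or a solitary stone with abnormal anatomy → II; otherwise I).

All band edges and rule tables live in `score_rules.yaml`, loaded into a
frozen `ScoreRules` object; the scoring functions are pure functions of
`(StoneProfile, ScoreRules)`.

Conventions that required a decision:

* **Area formula.** A stone's cross-sectional area is `length × width`
  (rectangle). The original S.T.O.N.E. definition uses L×W, and the SHA.LIN
  burden is described the same way; an `ellipse` option (π/4 · L·W) is
  provided for sensitivity analyses but is not the default.
* **Band closures.** SHA.LIN closes its boundaries on the printed side:
  burden 400 mm² scores 2 points, tract 100 mm scores 1, mean HU 950 scores
  1. S.T.O.N.E.'s density boundary is `< 950 / ≥ 950` — deliberately the
  opposite closure, following its source definition — so 950 HU scores 1
  SHA.LIN density point but 2 S.T.O.N.E. points.
* **Zero calyces.** A purely pelvic stone involves no calyx; 0 falls in the
  0–2 band (1 point).
* **Merged anatomy category.** The profile's
  `diverticulum_or_partial_staghorn` class cannot distinguish a diverticulum
  stone from a partial staghorn. Consequently the S.T.O.N.E. calyx
  component awards its 3-point staghorn value only for `complete_staghorn`;
  the merged class falls back to the calyx-count rule. The maximum total of
  13 is still attainable (via complete staghorn), matching the top printed
  stratum (9–13).
* **Hydronephrosis** is consumed as a pre-graded 3-level ordinal
  (none/mild, moderate, severe); grading it from images is out of scope.
* Band inputs are real-valued, so the integer band labels "0–399 / 400–799"
  are implemented as half-open intervals `[0,400), [400,800), [800,1600),
  [1600,∞)`.

Range facts, verified by exhaustive enumeration over the component
cross-products (384 SHA.LIN combinations, 96 S.T.O.N.E. combinations):
SHA.LIN attains exactly the totals 6…17, S.T.O.N.E. exactly 5…13, and each
total lies in exactly one stratum.

## Cohort model and derived variables

A cohort is one row per patient (CSV, UTF-8, `.` decimal point; stones
serialised as `"LxW;LxW"`, the five HU points as a semicolon list; booleans
as `true`/`false`). Derived variables:

* **EBL** = collected fluid volume − irrigation volume (negative values are
  rejected as physically impossible); dichotomised at 250 ml with exactly
  250 in the *low* group (the printed grouping uses strict `> 250`, so a
  convention was needed at the boundary).
* **Stone-free status** = largest residual fragment strictly < 4 mm.
* **Complication** = presence of any Clavien-Dindo grade; grades are
  consumed as labels, never inferred.

A row may carry either the raw measurement (residual size; the fluid-volume
pair) or the derived label (SFS; EBL); when both are present — as happens
after `attach_scores` writes its derived columns — they must agree, and the
raw measurement is authoritative on re-read.

The cohort summary ("table one") uses a *fixed* per-variable reporting
policy rather than a data-driven normality test, so the layout is
deterministic: age is reported mean ± SD with a t-test; BMI, burden, HU,
haemoglobin change, operative time, stay and the three scores are median
(IQR) with Mann-Whitney U; categoricals are counts (%) with chi-squared,
switching to Fisher's exact on a 2×2 table when any expected cell count is
below 5. Binary indicators (e.g. complications) are treated as categoricals
under this policy. Empty groups and empty strata are reported with explicit
markers (`n = 0`, undefined rate) rather than silent NaNs.

## Synthetic cohort generator

The generator emulates a retrospective PCNL cohort. Per patient, a latent
standard-normal "complexity" factor `z` tilts stone count (1 + Poisson with
log-rate linear in `z`), per-stone size (log-normal, location linear in
`z`), hydronephrosis and anatomy class (cumulative-logit on `z`), tract
length and calyx involvement — inducing the positive co-variation of
burden, multiplicity, obstruction and staghorn anatomy seen clinically.
HU density, demographics (age ≈ N(49, 11.4²), 60% male, BMI log-normal
around 24.4 kg/m²) and laterality are independent of `z`.

Outcomes are linked to the computed SHA.LIN total (switchable to S.T.O.N.E.
or Guy's via `outcome_score`), not to the latent features, so the
generative truth sits on exactly the scale the estimation pipeline
estimates — which is what makes clean parameter-recovery tests possible:

* stone-free: logit-linear, slope −0.56 per point;
* high blood loss (EBL > 250 ml): logit-linear, slope +0.309 per point,
  with a compatible continuous volume pair (irrigation ≈ N(3000, 400) ml,
  collected = irrigation + EBL) so the subtraction path is exercised;
* haemoglobin change: linear, +0.083 mg/dl per point, noise SD 0.6;
* operative time: linear, +0.854 min per point, noise SD 18;
* postoperative stay: log-normal around 7 days, deliberately
  score-independent (slope 0) to serve as the null outcome;
* complications: logit-linear, slope +0.34 per point; severity grades are
  drawn with the I:II:III:IV mix 49:38:21:3 among complicated patients.

The slope magnitudes are the per-point regression coefficients reported for
this family of scores; the intercepts were calibrated once, by large-n
simulation, so that a large default cohort shows ≈ 69.7% stone-free, ≈ 20%
high blood loss and ≈ 31% complications, with strictly monotone stone-free
(decreasing) and complication (increasing) gradients across the four
SHA.LIN strata and SHA.LIN discrimination of non-stone-free status in the
AUC 0.75–0.90 band. These defaults are fixed study conditions, not tuning
knobs.

Randomness discipline: one root `SeedSequence` spawns an independent
substream per patient, so a fixed seed fixes the cohort byte-for-byte after
canonical CSV serialisation and extending `n` never perturbs earlier
patients.

What the generator does **not** emulate: measurement and inter-observer
error in CT readings, correlation between density and burden, informative
missingness, staged or bilateral procedures, centre effects, or any
patient-level feature→outcome pathway that bypasses the score. Passing
tests therefore demonstrate that the pipeline is internally correct and
recovers known generative structure — not that the score's clinical
performance would replicate on real data.

## Inference

Group comparisons follow the fixed policy above. Regressions treat the
scores as continuous integer covariates (per-point odds ratios); the
adjusted models use the ten-covariate set — age, sex, BMI; stone burden
(continuous mm²), mean HU, stone count, side; anatomy class, tract length
(continuous mm), hydronephrosis — entered simultaneously ("enter" method,
no stepwise selection). Categorical covariates are dummy-coded against
their first level. Inference is Wald-based (normal-approximation CIs and
p-values, matching common clinical-statistics defaults), two-sided, with no
multiple-testing correction. Chi-squared statistics are uncorrected
(no Yates continuity correction) by default, switchable.

Numerical safeguards: the design matrix's rank is checked before fitting
(rank deficiency raises an error listing the aliased columns, found via
pivoted QR); a condition number above 1e8 attaches a warning, since
adjustment covariates overlap the score's own components; perfect
separation and non-convergence raise a dedicated error naming the
predictor; a constant outcome is rejected. Model fitting itself is
delegated to statsmodels (Logit/OLS).

## Discrimination

ROC curves sweep the unique observed score values (descending, with a `+∞`
sentinel; a case is called positive when score ≥ threshold). The positive
class is the adverse outcome (non-stone-free, complication, high EBL) so a
useful score has AUC ≥ 0.5. AUC is the trapezoid area; because integer
scores are heavily tied, the implementation carries a mandatory dual-route
cross-check against the tie-corrected pairwise-concordance (Mann-Whitney)
statistic, which must agree to 1e-12. The 95% CI uses DeLong's
structural-components variance with midranks, clipped to [0, 1]; under
perfect separation the variance degenerates and the CI collapses to the
point estimate with a warning. The optimal cutoff maximises Youden's
J = sensitivity + specificity − 1, with ties broken toward the
higher-specificity threshold; the returned cutoff is always an observed
score value or the sentinel.

## Problem sizes used in the test suite

Exhaustive enumerations are exact and instantaneous. Monte-Carlo checks use
n = 5000 cohorts: one for the calibration surface, and 100 replicate seeds
for parameter recovery (coverage of the SFS logistic slope and haemoglobin
linear slope by their 95% CIs, and the PLOS null's p > 0.05, each required
in ≥ 90/100 replicates — the Monte-Carlo-conservative version of nominal
95% coverage). The DeLong coverage experiment uses 100 replicates of a
binormal model with known AUC 0.83 at 150 cases per class.

## Known limitations

* Guy's and S.T.O.N.E. rule tables are encoded from their original
  definitions at the granularity the `StoneProfile` supports; the merged
  diverticulum/partial-staghorn category (above) is the one place the
  encoding is coarser than the source systems.
* The generator's outcome links are single-index (everything flows through
  one score); it cannot express outcomes driven by individual components.
* `summarize_cohort` requires a binary grouping variable.
* No paired AUC-difference test between scoring systems is provided; AUCs
  are reported side by side with their own CIs.
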