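# Methods

## The score and its encoding

The iBOX is the linear predictor of a Cox proportional-hazards model for
death-censored graft loss, evaluated from a single posttransplant
assessment. The packaged weights are the natural logarithms of the
published hazard ratios, stored to the printed two- or three-figure
precision (`data/coefficients_v1.csv`); the unrounded derivation-study
coefficients are not public, so the printed HRs are treated as the
source of truth. Using natural logs is the only convention under which
`exp(coefficient)` reproduces the printed HRs, which fixes the
"log-transformed UPCR" ambiguity the same way: proteinuria enters as
`ln(max(UPCR, 0.05))`, with the 0.05 g/g floor applied before the log.

Encoding rules with room for interpretation, and the choices made:

- **DSA cutoff.** MFI = 1,400 exactly is positive (the published
  categorization is "< 1,400" vs "≥ 1,400").
- **Paired Banff factors.** g+ptc and i+t are integer sums of the two
  component lesion scores, categorized afterwards (0–2 / 3–4 / 5–6 and
  0–2 / ≥3). Each categorical factor expands to one indicator per
  non-reference level, at most one set.
- **eGFR** enters uncapped; values above 120 mL/min/1.73 m² are
  physiologically implausible at 1 year and trigger a warning but are
  not altered.
- **Time from transplant** is a covariate in years; fractional values
  support assessments anywhere in the 6–24-month window.

The score is unitless (log-hazard scale) and unbounded; in clinically
ordinary ranges (eGFR 40–80, UPCR ≤ 1 g/g, DSA-negative, mild lesions)
it is negative, roughly −4 to −1.

## Absolute risk and the missing baseline

The qualification publishes no baseline survival, so absolute risk at a
horizon is only computable against a cumulative baseline hazard H0
estimated from some cohort. `breslow_baseline` implements the Breslow
step estimator with the scores as fixed (not refitted) linear
predictors; with all scores zero it reduces to Nelson–Aalen. Every
`BaselineHazard` carries a provenance tag (`estimated-from-cohort` /
`user-supplied`) that propagates into validation reports, so
cohort-derived risks are never silently presented as qualified model
predictions. Horizons beyond the baseline's support are clamped to the
last estimated value with a warning rather than extrapolated.

Event probability is `1 − exp(−H0(t)·e^score)`: monotone in both score
and horizon, 0 at t = 0.

## Validation statistics

**Discrimination** is Harrell's c under censoring. A pair is usable iff
the member with the strictly shorter observed time had an event; pairs
with tied observed times are not usable; tied scores count 1/2. The
statistic is the concordant fraction over usable pairs; with all scores
tied it is 0.5 by construction. Subjects censored after the assessment
remain in the pair set under these standard rules — no administrative
truncation at the prediction horizon is applied to discrimination
(truncation applies only to calibration). The standard error is a
leave-one-subject-out jackknife, computed in O(n²) from per-subject
pair totals; it is assumption-light where the published tables do not
state their SE method.

**Calibration** compares observed events O with the model-expected
count E = Σᵢ P(event by horizon | scoreᵢ) via z = (O − E)/√E with a
two-sided normal p. This is the single-stratum reduction of the
Poisson-regression calibration approach, without continuity
correction; that concretization reproduces all four published external
validation p-values (.20, .08, .51, .44) from their printed O/E pairs
at two decimals. (One published CNI-free subgroup row prints p = .26
where this test gives ≈ .19 from its O/E pair; the test variant behind
that single row is unstated, and no assertion in this package depends
on it.) Under a true Poisson null with E ≥ 10 the test holds its 5%
size to within ~1.5 points (checked at E = 10, 15, 25 with 10,000
replicates).

`validate_cohort` excludes subjects with no assessment or with an
assessment further than a configurable window (default ±0.5 y) from
the stated time, itemizes the exclusions, and reports n after
exclusion. Observed events for calibration are graft losses by the
horizon; death with a functioning graft censors.

## Survival machinery

Kaplan–Meier estimation is delegated to lifelines; Greenwood variance
is computed from the fitted event table (lifelines exposes
log-transformed intervals, not the plain Greenwood SE). The two-group
Cox fit is a one-parameter Newton maximizer of the partial likelihood
written directly (gradient and Hessian in closed form for a binary
covariate), with Breslow tie handling by default and Efron optionally —
the published analyses do not state their tie method, and at realistic
tie rates the two differ negligibly. The implementation agrees with
lifelines' `CoxPHFitter` to ~1e−5 and with a brute-force
partial-likelihood grid maximizer to 1e−4 on small data (both checked
in tests). When one arm has no events the partial likelihood is
monotone; the fit then returns a bounded estimate (|log HR| ≤ 20)
flagged non-convergent with no SE or p, rather than a spurious number.

## Trial endpoint and imputation

Subjects who lose their graft, die, or are lost to follow-up before the
scheduled assessment receive a worst-case score. The default policy is
**worst-rank**: maximum computed score + ε (ε = 0.1), which is exactly
what rank-based downstream analyses need and makes the order property
assertable (every imputed score exceeds every computed one). A
**worst-bounds** policy instead scores a configurable worst covariate
profile (default: eGFR 10, UPCR 3 g/g, DSA-positive, IFTA 3, g+ptc 5–6,
i+t ≥ 3, cg ≥ 1) for uses that need a concrete value on the score
scale; it is also the fallback when a cohort has no computed scores at
all. A subject with neither an assessment nor an observed end of
follow-up before the assessment time is a data-integrity error, never
silently imputed. The numeric meaning of "worst-case" is a policy
choice logged at run time, not a published constant.

Arms are compared three ways: difference in median scores (bootstrap SD
with ≥ 2,000 seeded resamples; two-sided Wilcoxon rank-sum p, exact for
combined n ≤ 20, normal approximation with tie correction otherwise —
a distribution-free default since the published analyses do not state
their test), per-arm Kaplan–Meier survival at the horizon with
Greenwood SE, and the two-group Cox log HR. Swapping arm labels negates
the median difference and the log HR.

**Power** is Monte-Carlo: simulate the two arms at each candidate
per-arm n, apply imputation, and count rank-sum rejections at α. The
binomial MC standard error is reported per point; the sample-size
recommendation reads off an isotonic (non-decreasing in n) smoothing of
the curve, which is more robust to MC noise than root-finding. Effects
can be specified as generator overrides (e.g. a higher eGFR mean) or as
a direct additive score shift; the latter exists so the engine can be
calibrated against the closed-form power of a location shift.

## The synthetic cohort generator

The cohorts behind the published validation are proprietary, so the
generator emulates their statistical shape rather than their data:
covariates drawn cross-sectionally at a fixed assessment time
(truncated-normal eGFR 55 ± 20; log-normal UPCR, median 0.15 g/g,
log-SD 1; DSA positivity 15% with MFI drawn on the matching side of
1,400; mild-lesion-dominant Banff categories), and event times drawn by
inverse transform from exactly the proportional-hazards model the score
assumes, S(t | score) = exp(−H0(t)·e^score). The default baseline is
Weibull with shape 0.8 (declining hazard, mimicking early transplant
failure) and rate 0.2, giving ~5% 5-year death-censored events and
~7% pre-assessment failures at the defaults; an exponential baseline is
retained because it admits closed-form checks. Censoring is independent
exponential (3%/y) plus a 7-year administrative cap; death with
function is an independent 2%/y process. One master seed spawns
per-stage substreams (covariates / event times / deaths / censoring),
so regeneration is bit-identical and changing one stage's draw count
does not perturb the others.

These defaults put 1-year full-score medians near −2.9 and model-true
c-statistics around 0.72–0.82 — the clinically observed regime — without
claiming to reproduce any unavailable dataset. What passing simulation
tests show is that the pipeline is correct *under the score's own
model*: real cohorts add measurement error, non-proportional hazards,
center effects and informative censoring that the generator
deliberately omits, so simulated performance says nothing about how
well the score discriminates in any particular clinic's data.

Parameter-recovery runs use a near-degenerate covariate configuration
(spreads ~0, treated arm's baseline rate scaled by e^δ) so that the
marginal two-group hazard ratio equals the conditional δ; with
heterogeneous covariates omitted from the fit, the marginal estimate
would be attenuated — a property of Cox models, not an implementation
error.

## Problem sizes and numerics

Test and demonstration runs use cohorts of 200–2,000 subjects, 100–300
Monte-Carlo replicates for power points, 2,000 bootstrap resamples, and
10,000 replicates for size checks of the calibration test — sizes at
which the quantities of interest are stable to within the tolerances
asserted. Newton iterations stop at |Δβ| < 1e−10 with estimates bounded
at |β| ≤ 20; concordance and its jackknife are exact O(n²) matrix
computations, not approximations. Degenerate inputs are contracts, not
crashes: no events anchors no baseline (error), all-censored KM is flat
at 1, no usable pairs yields an explicitly undefined concordance,
O = E = 0 calibrates perfectly.

## Known limitations

- The packaged coefficients inherit the rounding of the published HRs;
  scores are reproducible to that precision only.
- Absolute risks depend entirely on the user- or cohort-supplied
  baseline hazard; the package cannot reproduce the published absolute
  predictions because no baseline was published.
- The published validation c-statistics, subgroup tables and trial
  medians derive from proprietary cohorts and are not reproducible
  here; the package validates itself on generated data instead.
- Single-assessment (cross-sectional) scoring only: no longitudinal
  eGFR trajectories, center effects, or competing-risks modelling.
- eGFR and Banff grades are taken as given; computing eGFR from
  creatinine or grading biopsies is out of scope.
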