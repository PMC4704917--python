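# Methods

This note documents the models, parameter choices and numerical
conventions behind `dietval`, and what the synthetic-data tests do and do
not demonstrate.

## Energy intake from food records

Daily energy intake (EI) is the sum over meals and items of
`grams/100 × energy_kj_per_100g`, with portion units converted to grams
through per-food gram weights (a `gram` unit with weight 1 always
exists). Nutrients aggregate identically. The kcal↔kJ factor is fixed at
4.184 kJ/kcal everywhere; it reproduces the conventional integer pairs
500 kcal = 2092 kJ and 200 kcal = 837 kJ. Supplements recorded in the
evening questions never enter energy or nutrient totals. A day is the
calendar date 00:00–24:00, with no timezone arithmetic.

## Basal metabolic rate and questionnaire-based TEE

BMR uses Schofield's weight-only linear equations in kJ/day,
`BMR = a·W + b`, with coefficients per sex and age band kept in one
auditable table (`physiology.SCHOFIELD_KJ`). Age bands are half-open
`[lower, upper)`: a participant aged exactly 18.0 falls in the 18–30
band. For the cohort of interest the 10–18 band applies (girls
`56·W + 2898`, boys `74·W + 2754`). Age is the exact decimal year count
between birth date and the evaluation reference date (365.2425 d/y).

Questionnaire-based expenditure is `TEE_app = BMR × PAL`, where PAL
comes from a five-level self-report with sex-specific multipliers —
girls 1.3 / 1.5 / 1.7 / 1.9 / 2.1, boys always +0.1 — chosen to give a
wide dispersion of TEE from a single evening question.

## Reference TEE from armband traces

A trace is 1440 minute slots of (EE kJ, on-body flag). Wear time is the
on-body minute count / 60. Daily reference TEE sums the on-body minutes
and imputes each off-body minute at the basal rate `BMR/1440`, mirroring
how the device itself reports basal expenditure when removed; hence
`TEE_SWA ≥ Σ on-body EE` with equality iff fully worn.

## Anthropometrics

BMI z-scores use the LMS transform `z = ((BMI/M)^L − 1)/(L·S)` with
linear age interpolation, and weight status compares BMI to age/sex
cutoff curves (thinness grades 2 and 1, overweight, obese), boundaries
inclusive toward the more extreme category. The shipped reference
(`data/lms_reference_synthetic.csv`, ages 14–18 by half-years) is a
**synthetic** stand-in: smooth L/M/S curves with cutoffs back-projected
from the adult BMI anchors 16/17/25/30 through the same curves — the
construction of the international child references, but not their
published values. Analyses of real data should substitute the published
table; the API accepts any conforming CSV.

## Questionnaire scoring and imputation

Instrument composition (item counts, response-scale bounds, reverse-keyed
items, the TFEQ-R18 subscale partition CR = {2,11,12,15,16,18},
UE = {1,4,5,7,8,9,13,14,17}, EE = {3,6,10}) lives in a JSON config
(`data/instruments.json`); the scale content of the borrowed instruments
is declared configuration, not a transcription of the originals. Every
multi-item scale maps linearly onto 0–100:
`100·Σ(item − min) / (n·(max − min))` after flipping reversed items.
Whether the original analyses used exactly this linear transform or
instrument-specific scoring is not derivable from the summary statistics
we anchor to; the config permits either, and the linear transform is the
declared default because only the 0–100 range is fixed.

Imputation, applied before scoring: missing figure-rating answers become
*no discrepancy*; missing breakfast frequency becomes 7 days/week and
school lunch 5 days/week; missing conscientiousness items take the scale
midpoint; other missing scale items take the per-item median of the
remaining respondents (the published rule for social desirability,
uncontrolled eating and cognitive restraint, applied uniformly to the
remaining item scales); missing yes/somewhat/no answers take the modal
response. Imputing a complete collection is the identity, and every
imputed cell is logged.

## Evaluation pipeline

Days with EI strictly below 2092 kJ (500 kcal) are excluded; armband
days require wear ≥ 19 h (80% of the day), inclusive. Per participant,
EI, TEE_SWA and TEE_app are means of the included daily values over each
metric's own day set — the reference was worn on the same or proximate
days, so day matching is not required. Reporting classification uses
EI/TEE_SWA with a ±5% plausible band, boundaries inclusive (a convention
this package fixes openly; the band itself is the published rule).

Bland–Altman agreement uses differences x−y, the sample SD (n−1) and
limits of agreement mean ± 1.96·SD; two pairs are the computational
minimum (the SD needs two differences). Group, paired and correlation
contracts delegate to vetted routines (`scipy.stats`): Mann-Whitney U,
Wilcoxon signed-rank, paired t, Spearman with average ranks; identical
paired samples return p = 1.0 by convention rather than raising.

Reporting-accuracy regression: each candidate factor (sex, BMI z,
measured TEE, demographics, school, the six indices, body-size
discrepancy, the meal and attitude dichotomies, weekend day in record)
is first fit alone by OLS with 95% CIs; forward stepwise selection then
adds the smallest-p candidate while p < .05 and prunes included terms
whose p exceeds .10 (conventional defaults, overridable). Measured TEE
is excluded as a candidate for the relative outcome (EI−TEE)/TEE, which
already contains it. Categorical reference levels: parental education
`medium`, body-size discrepancy `no discrepancy`, school first
alphabetically. Rank-deficient designs raise an error naming the
collinear columns rather than silently dropping them. A mixed-model
check with a random school intercept is available to confirm selected
effects are not clustering artifacts.

The design-stage sample-size formula is `n = ⌈2·(2.8·SD/Δ)²⌉ `
(α = .05, 80% power for a paired difference).

## The synthetic-data generator

The generator emulates the target study design: n = 81 (50 girls),
age ≈ N(15.5, 0.37) within 14–16.5; girls' height N(164.9, 10.0) cm and
boys' N(176.5, 8.9); BMI z ≈ N(0.44, 0.62) drawn directly and inverted
through the LMS reference so weight follows from height and BMI;
1–6 recording days per participant with probabilities
(.12, .14, .67, .05, .015, .005) and weekday weights tuned to ≈40%
weekend days; true PAL ≈ N(1.48, 0.15) per participant with 5% daily
wobble; armband wear gaps gamma-distributed (mean 60 min, SD 45 min),
giving ≈23 h mean wear.

Reported intake follows `EI(i,d) = TEE_true(i,d) × ratio_i × day-noise`,
with day-to-day CV 0.25 (a declared free parameter — within-person
variance is not derivable from the group summaries we anchor to) and
`log ratio_i ~ N(log 0.71 + (slope/0.71)·(z_i − z̄), 0.33²)`. The
between-person σ of 0.33 reproduces the anchor cohort's EI/TEE spread
(IQR ≈ 0.36) once day and device noise are added. Multiplicative noises
are mean-one log-normal so day-averaging is unbiased; the reporting
ratio is *median*-centred because the recovered cohort statistic is a
median. The BMI-z gradient (default −0.13 per z-unit on the EI/TEE
scale) and the weekend shift (default +1557 kJ/day of accuracy for
records containing a weekend day) are injected so the accuracy
regressions can be validated by CI coverage; the weekend shift is placed
on the weekend days but scaled so the record-level effect equals the
configured value exactly, and it is centred across the cohort so the
group-level ratio target is preserved. The armband day total is
`TEE_true ×` mean-one noise (CV 0.10) distributed over a diurnal minute
profile; the evening activity answer is the PAL level nearest to
`PAL_true × 1.19 ×` noise, so questionnaire TEE overstates the armband
1.19-fold at the median. Meals are composed greedily from the generated
food database (12 groups × 5 items; energy = 17·protein + 17·carb +
37·fat kJ per 100 g exactly) so the record's computed energy matches the
day's EI to within 1%; menu realism is explicitly not a goal.
Questionnaire missingness mirrors the anchor study's per-field counts
(≈19% of participants with any missing answer), scaled by a single
knob.

What passing tests show — and don't. Parameter recovery on this
generator demonstrates that the pipeline's arithmetic, filters,
classification and regressions are correct and unbiased under the
generative model. It does not validate the generator against real
adolescents: real records have correlated meal patterns, non-log-normal
reporting bias, device-specific armband error structure and informative
missingness, none of which are modeled.

## Problem sizes and determinism

The recovery checks use twenty seeded replicates of the full n = 81
study (a few hundred milliseconds each end-to-end), which puts the
Monte-Carlo SE of the seed-averaged cohort medians near 0.01 — small
against the ±0.03 recovery tolerance. All randomness flows from a single
`numpy` `default_rng` seed per study; the same configuration reproduces
a study bit-identically.

## Known limitations

* The Schofield variant is the weight-only one; height-and-weight
  variants exist and would change BMR by a few percent.
* The stepwise procedure mimics the conventional SPSS defaults; stepwise
  selection is known to overfit and is provided for fidelity, not as a
  recommended modeling strategy.
* The LMS fixture is synthetic (above); z-scores and weight-status
  proportions from it are internally consistent but not comparable to
  published prevalence figures.
* The two-method comparison treats the second method as an independent
  paired measurement; shared-error structure between two food records is
  not modeled.
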