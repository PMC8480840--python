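# Methods

## The analysis this package implements

Wrist-accelerometer studies summarise each participant's week of wear as
1-minute epochs, each carrying the epoch's mean vector magnitude (in
milligravities, m-grav) and the per-axis standard deviations, plus an
optional machine-learning (ML) activity prediction. The pipeline turns these
epoch records into per-participant time-use compositions and relates them to
all-cause mortality with *coupling* (isotemporal substitution) Cox models:

1. **Non-wear detection.** An epoch is stationary when all three axis SDs are
   strictly below 13.0 m-grav; every maximal run of at least 60 consecutive
   stationary epochs is treated as non-wear (missing). The device is
   sensitive enough that genuine wear shows per-axis SDs above this
   threshold.
2. **Epoch classification.** The *hybrid* rule labels worn epochs with vector
   magnitude ≥ 100 m-grav as MVPA (moderate-to-vigorous physical activity),
   takes sleep and sedentary from the ML prediction among the remaining
   epochs, and assigns every other worn epoch — including ML "walking" and
   epochs without a prediction — to light activity. An *ML-only* sensitivity
   rule uses the ML prediction for every category (no threshold), with the
   walking class merged into light by default (`walking_policy`), keeping a
   four-part composition commensurate with the main analysis.
3. **Missing-data handling.** The *complete days* sample uses calendar days
   with no missing epochs ("valid" days). The *other day* imputation fills
   each maximal missing run with the same clock-time window from another
   day, chosen uniformly at random among days whose window is fully
   observed (days missing data at other times remain eligible). Participants
   need ≥ 72 h of observed wear and ≥ 1 valid day to enter an analysis
   sample.
4. **Bouts and summaries.** A bout is a maximal run of consecutive epochs in
   one category; bouts may span midnight between adjacent valid days but not
   an invalid day. Sedentary time is stratified into bouts of 1–15, 16–40,
   and 41+ minutes; MVPA into 1–9, 10–15, 16–40, and 41+ minutes. Every
   minute counts toward the stratum of its bout's total length and toward
   the calendar day on which it occurs, so per-day totals close to 1,440
   minutes while bout-length semantics are preserved. Per-participant
   summaries are averages over valid days; the four category averages sum
   to 1,440 min/day exactly and each stratum set partitions its category.
5. **Coupling Cox models.** Because the composition components partition the
   1,440 minutes of a day, one *baseline* component is omitted from the
   model; the coefficient of a remaining component k, with components scaled
   per 10 minutes, is the log hazard ratio of spending 10 min/day more in k
   coupled with 10 min/day less in the baseline. Models run on the age time
   scale with left truncation at entry age (age at the end of accelerometer
   wear; birth is taken as July 1 of the birth year so ages are fractional
   years) and right censoring at exit age. Covariates: sex, ethnicity,
   smoking, education, income, Townsend deprivation, seasonal terms
   c1 = cos(2πd/365) and c2 = sin(2πd/365) for wear day-of-year d, and — in
   the full set — BMI and three prevalent-disease indicators; a
   `no_bmi_no_illness` set drops the last four as a mediation-sensitivity
   option. Delayed-entry sensitivity shifts entry by 1 or 2 years, dropping
   participants whose exit precedes the delayed entry.

## Synthetic cohorts

No public individual-level accelerometer cohort with linked mortality is
redistributable, so the package ships a generator that emulates the
statistical structure the analysis assumes, with known truths for
parameter-recovery testing.

**Activity.** Each participant's week is a semi-Markov chain over
sleep/sedentary/light/MVPA. Dwell (bout) lengths are geometric by default
(memoryless at the minute scale; a shifted negative binomial is available),
with means 200/40/10/3 minutes — sedentary time accumulates in long bouts
and MVPA in very short ones, the qualitative pattern seen in real wrist
data. Category switches never repeat the current category; selection
weights are multiplied, for sleep, by a diurnal factor (×8 between 22:00 and
06:30, ÷8 otherwise), which concentrates sleep at night without a hard
clock schedule. Default weights give mean compositions near 540/535/300/65
min/day. Simulated wear starts at local midnight so the n_days × 1,440
epochs align with calendar days; a mid-day device start is available via
`start_clock_minute` (its partial first/last days are then never valid).

**Measurement layer.** Per-epoch vector magnitude is drawn from
category-specific gamma distributions (MVPA shifted above 100 m-grav, so
threshold misclassification of true MVPA is absent by default while some
light activity exceeds 100); axis SDs are drawn shifted above the 13 m-grav
stationarity threshold so injected non-wear is the only stationary signal —
a deliberate simplification of real wrist data, where long motionless sleep
can resemble non-wear. ML labels come from a row-stochastic confusion
matrix whose default diagonal follows the published classifier's headline
accuracies (91% sleep, 25% light, 58% MVPA). Non-wear episodes arrive at a
Poisson rate (default 0.3 per week) with 60-minute-minimum shifted-
exponential durations and overwrite emissions with stationary values.

**Confounding and survival.** Baseline covariates follow roughly the
marginal distributions of a large UK cohort of 60-year-olds; configurable
coefficients link them both to activity propensity (e.g. higher BMI, current
smoking and prevalent cardiovascular disease lower the MVPA selection
weight) and directly to the death hazard, plus lognormal person-level
heterogeneity in activity propensity. Death ages are drawn by inversion
from a piecewise-constant baseline hazard on age (default bands rising from
2.5×10⁻⁴/year at 40–55 to 0.02/year above 85), multiplied by
exp(Σ β_k·minutes_k/10 + covariate effects), conditional on survival to the
uniform entry age (48–76 years), with administrative censoring at age 82.
The default truths are the reference values HR 0.96 per 10 min MVPA-for-
light and 1.02 per 10 min sedentary-for-light, which imply 1.06 for
sedentary-for-MVPA and 0.94 for MVPA-for-sedentary. Survival depends on the
*true* (pre-noise, pre-missingness) composition, so classification error,
non-wear and imputation can be studied as deviations, and recovery of the
true coefficients by the coupling model is a well-defined target.

**Reproducibility.** All randomness flows from one master seed with a fixed
splitting rule: `SeedSequence([seed, 0])` for covariates and propensity
heterogeneity, `([seed, 1, i])` for participant i's activity sequence, and
`([seed, 2])` for survival draws. Identical config + seed reproduces a
cohort byte-identically, including under partial regeneration.

**What the generator does not emulate.** Raw 100 Hz signals, calibration
artefacts and device-specific noise; within-category intensity variation;
day-to-day autocorrelation of activity beyond the diurnal cycle;
informative (activity-dependent) non-wear; measurement error acting on
survival (by construction). Passing recovery tests therefore demonstrates
the statistical machinery is correct under the stated data-generating
assumptions, not that real-cohort estimates are unbiased.

## Numerical and design choices

- **Thresholds** are read literally: MVPA at vm ≥ 100 (inclusive),
  stationarity at sd < 13.0 (strict), non-wear at runs ≥ 60 min, strata as
  closed integer intervals on whole-minute bout lengths.
- **Ties.** Fits use lifelines' Cox partial likelihood, which implements the
  Efron approximation; ages are continuous so heavy ties do not arise. The
  model spec records the tie method and accepts only `efron`.
- **Confidence intervals** are Wald intervals on the log scale, the standard
  reporting convention for hazard ratios; p-values are unadjusted per
  contrast (no multiplicity correction across the coupling grid).
- **Degenerate model columns** (an unobserved categorical level in a small
  sample, or an empty bout-length stratum such as 41+ minute MVPA bouts
  under the default short-bout regime) are dropped from a fit with a logged
  warning rather than producing a singular model.
- **Schoenfeld residuals** are computed directly (event covariates minus the
  exp(Xβ)-weighted risk-set mean, risk set `entry < t ≤ exit`) because the
  diagnostic must respect left truncation; they are cross-checked against
  lifelines' residuals in the no-truncation case. Scaled residuals use the
  Grambsch–Therneau form d·r·V̂(β̂) + β̂; the PH statistic is the Pearson
  correlation of scaled residuals with log(event age), with a t-test
  p-value (df = events − 2). Simulation shows type-I error ≈ 0.05 under
  exact proportional hazards.
- **ILR sensitivity.** The isometric log-ratio fit uses the sequential
  binary partition (sleep | sedentary, light, MVPA), (sedentary | light,
  MVPA), (light | MVPA) by default (configurable); zero parts are replaced
  by 0.5 min — half the minimal observable bout at 1-minute resolution —
  before re-closing to 1,440. Because the ILR model is linear in log-ratios
  rather than minutes, its implied 10-minute substitution contrasts
  (evaluated at the mean composition) agree with the per-10-minute model in
  sign and ordering, but not in magnitude for small parts such as MVPA.
- **Baseline-switch identity.** For any closed composition, refitting with a
  different omitted component must reproduce coefficients via
  β′_k = β_k − β_b′; this holds to < 10⁻⁶ and is tested.
- **Imputation** operates on classified label sequences rather than raw
  signal (downstream summaries depend only on labels); donor choice is
  uniform; missing runs crossing midnight are split at the boundary because
  same-clock-time matching is otherwise ill-defined; each interval draws its
  donor independently. The 72-hour inclusion rule counts observed (not
  imputed) wear.
- **Problem sizes.** Recovery experiments in the test suite use 50 replicate
  cohorts of n = 5,000 (each with well over 400 events); the acceptance
  script uses 30 cohorts of n = 4,000. At these sizes the Monte Carlo
  standard error of the mean log-HR is a few 10⁻³, comfortably inside the
  0.005 bias budget, and the per-coefficient CI-coverage check uses a 99%
  binomial tolerance around 0.95.

## Known limitations

- The joint distribution of activity and covariates is illustrative, not
  calibrated to any cohort's microdata; only the marginals are loosely
  matched.
- Administrative censoring is a single age rather than a calendar date, so
  follow-up length varies more with entry age than in a real cohort with a
  fixed study end date.
- The generator's category-level true effects imply equal effects across
  bout-length strata; bout-length models can be fit and recover those
  equalities, but differential bout-length effects are not simulated.
- ML-only classification with `keep_separate` walking produces a five-part
  composition that the standard four-part summaries refuse; it is intended
  for label-level inspection only.
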