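# actcouple

Isotemporal **coupling** analysis of accelerometer time use and all-cause
mortality: a tested pipeline from minute-epoch wrist-accelerometer records
to hazard ratios for 10-minute/day activity substitutions.

A day has 1,440 minutes, so spending more time in one activity category —
sleep, sedentary, light activity, or MVPA (moderate-to-vigorous physical
activity) — necessarily means less time in another. The package estimates
the mortality hazard associated with such *couplings*: designating one
category (or bout-length stratum) as the baseline and fitting a Cox
proportional-hazards model on the age time scale whose remaining
composition components enter per 10 minutes/day,

    h(a | x) = h0(a) · exp( Σ_{k ≠ baseline} β_k · m_k / 10 + γ'z ),

where m_k is average daily minutes in component k and z are confounders.
Because Σ_k m_k = 1,440, omitting the baseline identifies exp(β_k) as the
hazard ratio (HR) for 10 min/day more of component k coupled with 10
min/day less of the baseline. Supporting machinery covers the full journey
from raw epoch summaries: non-wear detection (all three axis SDs
< 13.0 m-grav for ≥ 60 min), hybrid epoch classification (vector magnitude
≥ 100 m-grav → MVPA, then ML predictions for sleep/sedentary, remainder →
light), "other day" imputation of non-wear gaps, activity-bout derivation
with bout-length strata (sedentary 1–15/16–40/41+ min; MVPA
1–9/10–15/16–40/41+ min), seasonal cosine covariates, delayed-entry and
isometric log-ratio (ILR) sensitivity analyses, and a Schoenfeld-residual
proportional-hazards diagnostic.

It is aimed at epidemiologists and biostatisticians who want to apply or
study compositional time-use survival analysis. Individual-level cohort
data of this kind are access-restricted, so the package includes a
first-class synthetic-cohort generator with realistic bout structure,
confounding, and *known* substitution effects, making parameter recovery a
testable property. See `docs/methods.md` for the full model description.

## Worked example

Run the bundled demo (a 500-participant synthetic cohort) end to end:

```bash
actcouple run-all --config examples/demo_config.yaml \
    --outdir demo_out --baseline light
```

which prints the participant flow

```
stage                         in     out  exclusions
simulate                     500     500  -
classify                     500     500  -
impute                       500     500  -
summarize[complete]          500     500  -
fit[overall,complete]        500     500  -
```

and writes `demo_out/estimates_overall_complete.csv`:

```
baseline comparison     hr  ci_low  ci_high      p  ph_corr   ph_p   n  n_events
   light      sleep 0.9310  0.7862   1.1024 0.4069  -0.1164 0.2261 500       110
   light  sedentary 0.9466  0.7816   1.1465 0.5747  -0.1163 0.2265 500       110
   light       mvpa 0.8589  0.6360   1.1599 0.3211  -0.0954 0.3215 500       110
```

Each row is one coupling: e.g. the last row estimates HR 0.86 (95% CI
0.64–1.16) per 10 min/day more MVPA coupled with 10 min/day less light
activity, with the per-column proportional-hazards diagnostic (`ph_corr`,
`ph_p`). At n = 500 (110 deaths) the intervals are wide; they comfortably
cover the generator's true values (HR 0.96 for MVPA-for-light, 1.02 for
sedentary-for-light, sleep null). Larger cohorts recover the truths tightly
— see below. The same CLI exposes `--classifier ml-only`, `--impute none`,
`--mode imputed`, `--model sedentary-bouts|mvpa-bouts`, `--entry-delay 1|2`,
`--covariates no-bmi-illness`, and `--ilr`; the library API (`actcouple.*`)
offers the same operations on in-memory objects.

## Layout

- `src/actcouple/synthetic.py` — synthetic cohorts (semi-Markov activity,
  measurement layer, confounders, piecewise-exponential survival)
- `src/actcouple/classify.py` — non-wear detection, hybrid / ML-only epoch
  classification, valid days and inclusion
- `src/actcouple/impute.py` — other-day imputation
- `src/actcouple/bouts.py` — bouts, bout-length strata, participant summaries
- `src/actcouple/survmodel.py` — coupling Cox models, season covariates,
  ILR sensitivity, Schoenfeld PH diagnostics
- `src/actcouple/pipeline.py`, `cli.py` — stage orchestration, manifests,
  participant-flow reports, command line
- `tests/` — unit, property and acceptance tests (brute-force oracles in
  `tests/_oracles.py`)
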