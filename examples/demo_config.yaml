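admin_censor_age: 82.0
baseline_hazard:
  breaks:
  - 40.0
  - 55.0
  - 65.0
  - 75.0
  - 85.0
  rates:
  - 0.00025
  - 0.001
  - 0.0025
  - 0.006
  - 0.02
category_weights:
  light: 0.65
  mvpa: 0.2
  sedentary: 0.11
  sleep: 0.018
covariate_params:
  activity_coefs:
    mvpa:
      bmi: -0.04
      entry_age: -0.02
      prior_cvd: -0.25
      season_cos: 0.15
      sex: 0.1
      smoking_current: -0.3
      townsend: -0.02
    sedentary:
      bmi: 0.02
      prior_cvd: 0.1
  activity_re_sd:
    mvpa: 0.55
    sedentary: 0.25
    sleep: 0.15
  age_center: 62.0
  bmi_center: 26.7
  bmi_mean: 26.7
  bmi_sd: 4.5
  education_probs:
    degree: 0.45
    further: 0.175
    none: 0.075
    secondary: 0.3
  ethnicity_probs:
    asian: 0.009
    black: 0.008
    other: 0.013
    white: 0.97
  hazard_coefs:
    bmi: 0.02
    prior_cancer: 0.5
    prior_cvd: 0.4
    prior_respiratory: 0.15
    sex: 0.45
    smoking_current: 0.8
    smoking_previous: 0.2
    townsend: 0.04
  income_probs:
    18_31k: 0.242
    31_52k: 0.288
    52_100k: 0.252
    gt_100k: 0.073
    lt_18k: 0.145
  prior_cancer_p: 0.14
  prior_cvd_p: 0.31
  prior_respiratory_p: 0.41
  season_peak_day: 172
  sex_p_male: 0.455
  smoking_probs:
    current: 0.1
    never: 0.57
    previous: 0.33
  townsend_mean: -1.71
  townsend_sd: 2.82
dwell_params:
  light:
    dist: geometric
    mean: 10.0
  mvpa:
    dist: geometric
    mean: 3.0
  sedentary:
    dist: geometric
    mean: 40.0
  sleep:
    dist: geometric
    mean: 200.0
emission_params:
  light:
    sd:
      dist: gamma
      loc: 14.0
      scale: 10.0
      shape: 2.0
    vm:
      dist: gamma
      scale: 15.0
      shape: 4.0
  mvpa:
    sd:
      dist: gamma
      loc: 14.0
      scale: 25.0
      shape: 2.0
    vm:
      dist: gamma
      loc: 100.0
      scale: 40.0
      shape: 2.0
  sedentary:
    sd:
      dist: gamma
      loc: 14.0
      scale: 4.0
      shape: 2.0
    vm:
      dist: gamma
      scale: 8.0
      shape: 3.0
  sleep:
    sd:
      dist: gamma
      loc: 14.0
      scale: 3.0
      shape: 2.0
    vm:
      dist: gamma
      scale: 5.0
      shape: 3.0
entry_age_range:
- 48.0
- 76.0
epoch_minutes: 1
ml_confusion:
  light:
    light: 0.25
    mvpa: 0.1
    sedentary: 0.4
    sleep: 0.05
    walking: 0.2
  mvpa:
    light: 0.1
    mvpa: 0.58
    sedentary: 0.1
    sleep: 0.01
    walking: 0.21
  sedentary:
    light: 0.06
    mvpa: 0.02
    sedentary: 0.85
    sleep: 0.05
    walking: 0.02
  sleep:
    light: 0.02
    mvpa: 0.01
    sedentary: 0.05
    sleep: 0.91
    walking: 0.01
n_days: 7
n_participants: 500
nonwear_duration:
  dist: shifted_exponential
  mean: 300.0
  min: 60
nonwear_rate: 0.3
reference_category: light
seed: 20210915
sleep_diurnal_weight: 8.0
start_clock_minute: 0
true_log_hr:
  mvpa: -0.040821994520255166
  sedentary: 0.01980262729617973
  sleep: 0.0
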