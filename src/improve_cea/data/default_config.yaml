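# Base-case configuration: every model input with its uncertainty
# specification, analysis settings, risk-score coefficients and the
# synthetic-cohort sampling spec.  Edit a copy of this file and pass it via
# --config.  Currency: EUR-2022.
p_periop_stroke_death:
  family: beta
  params:
  - 235.0
  - 6224.0
periop_severity:
  family: dirichlet
  params:
  - 43.0
  - 34.0
  - 12.0
p_residual_3y_post_cea:
  family: beta
  params:
  - 166.0
  - 7423.0
residual_severity:
  family: dirichlet
  params:
  - 115.0
  - 80.0
  - 35.0
omt_severity:
  family: dirichlet
  params:
  - 81.0
  - 46.0
  - 25.0
evt_fraction:
  family: beta
  params:
  - 58.0
  - 942.0
mrs12_split:
  family: dirichlet
  params:
  - 55.0
  - 45.0
mrs345_split:
  family: dirichlet
  params:
  - 50.0
  - 30.0
  - 20.0
utilities:
  mrs0: 0.96
  nondisabling_first: 0.864
  nondisabling_recurrent: 0.812
  disabling: 0.356
  fatal: 0.0
  base: 0.918
  recurrent_decrement: 0.0524
  uncertainty_ess: 1000.0
costs:
  mri: 254.0
  cea: 8733.0
  nondisabling_first3m: 14511.0
  nondisabling_per_month: 999.0
  disabling_first3m: 45265.0
  disabling_per_month: 5865.0
  fatal_onetime: 13111.0
  baseline_per_month: 0.0
  gamma_cv: 0.2
timing:
  mean_months: 24.1
  sd_months: 2.7
timing_by_stenosis:
  lt50:
    mean_months: 34.2
    sd_months: 0.9
  s50_69:
    mean_months: 24.2
    sd_months: 1.4
  s70_99:
    mean_months: 10.7
    sd_months: 1.2
improve:
  baseline_survival_36m: 0.985
  age_center: 70.0
  beta_age: 0.03
  beta_male: 0.2
  beta_sten_50_69: 0.6
  beta_sten_70_99: 1.0
  beta_cerebral: 0.5
  beta_iph: 1.5
  s0_shape: 1.0
  conditional_window: next36
lifetime_qaly_per_mrs: null
lifetime_cost_per_mrs: null
wtp: 50000.0
horizon_months: 36.0
discount_cost: 0.04
discount_qaly: 0.015
cpi_factor: 1.265
mc_draws: 10000
cohort:
  n: 678
  age_mean: 71.0
  age_sd: 10.0
  age_min: 30.0
  p_male: 0.66
  index_event:
    tia: 0.42
    stroke: 0.44
    amaurosis_fugax: 0.14
  stenosis:
    lt50: 0.5
    s50_69: 0.3
    s70_99: 0.2
  p_iph: 0.43
  iph_by_stenosis: null
  days_since_event_median: 37.0
  days_since_event_log_sd: 0.8
  followup_median_months: 17.0
  max_followup_months: 72.0
  event_time_shape: 1.0
  mrs12_split:
  - 0.55
  - 0.45
  seed: null
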