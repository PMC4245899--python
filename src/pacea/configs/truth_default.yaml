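# Default synthetic-truth parameters for the registry generator and for
# running the Markov model directly from configured inputs.
#
# Hazard ratios / odds ratios are per deprivation quintile (1 = least
# deprived = reference).  Weibull models use cumulative hazard
# H(a) = exp(x beta) * a^gamma on the attained-age time scale; the
# "log_scale" entries are the reference-person (age 50, male, quintile 1)
# log scale parameter log(exp(beta0)).  Baseline levels (hazards at age 60,
# prevalences, mean costs) are package defaults chosen to be realistic for
# a UK primary-care population; the quintile gradients carry the registry
# evidence.

weibull_incidence:
  DM:      {shape: 5.0, log_scale: -23.285, female: -0.163, age: 0.0,
            quintile_hr: [1.0, 1.16, 1.29, 1.49, 1.76]}
  CHD:     {shape: 5.5, log_scale: -25.428, female: -0.357, age: 0.0,
            quintile_hr: [1.0, 1.10, 1.15, 1.27, 1.47]}
  STROKE:  {shape: 6.0, log_scale: -28.073, female: -0.105, age: 0.0,
            quintile_hr: [1.0, 1.15, 1.26, 1.27, 1.51]}
  CRC:     {shape: 5.0, log_scale: -24.489, female: -0.105, age: 0.0,
            quintile_hr: [1.0, 1.06, 1.05, 1.05, 1.04]}

weibull_mortality:
  shape: 8.0
  AT_RISK: {log_scale: -36.261, female: -0.223, age: 0.0,
            quintile_hr: [1.0, 1.09, 1.16, 1.31, 1.49]}
  # single-condition classes: log-hazard increment over the healthy baseline,
  # with class-specific quintile gradients
  DM:      {log_hr: 0.470, female: -0.223, age: 0.0,
            quintile_hr: [1.0, 0.92, 0.95, 1.04, 1.14]}
  CHD:     {log_hr: 0.642, female: -0.223, age: 0.0,
            quintile_hr: [1.0, 0.98, 1.03, 1.12, 1.19]}
  STROKE:  {log_hr: 0.833, female: -0.223, age: 0.0,
            quintile_hr: [1.0, 1.29, 1.12, 1.19, 1.37]}
  CRC:     {log_hr: 1.030, female: -0.223, age: 0.0,
            quintile_hr: [1.0, 0.77, 1.06, 1.25, 1.12]}

depression_logistic:
  AT_RISK: {intercept: -2.4423, age: -0.010, female: 0.405,
            quintile_or: [1.0, 1.15, 1.22, 1.44, 1.86]}
  DM:      {intercept: -1.8153, age: -0.010, female: 0.405,
            quintile_or: [1.0, 1.20, 1.33, 1.43, 1.83]}
  CHD:     {intercept: -1.7346, age: -0.010, female: 0.405,
            quintile_or: [1.0, 1.34, 1.33, 1.50, 2.01]}
  STROKE:  {intercept: -1.5163, age: -0.010, female: 0.405,
            quintile_or: [1.0, 1.12, 1.24, 1.28, 1.58]}
  CRC:     {intercept: -1.9924, age: -0.010, female: 0.405,
            quintile_or: [1.0, 1.01, 0.83, 1.36, 1.27]}

cost_two_part:
  gamma_shape: 1.2           # dispersion of positive annual costs
  AT_RISK:
    probit: {intercept: 0.674, age: 0.010, female: 0.10, depressed: 0.30,
             quintile: [0.0, 0.02, 0.04, 0.06, 0.08]}
    gamma:  {intercept: 5.8579, age: 0.015, female: 0.05, depressed: 0.35,
             quintile: [0.0, 0.02, 0.05, 0.08, 0.12]}
  # condition classes: intercept increments over AT_RISK (probit index and
  # log mean positive cost); other coefficients shared
  DM:      {probit_shift: 0.50, gamma_shift: 0.788}
  CHD:     {probit_shift: 0.50, gamma_shift: 0.956}
  STROKE:  {probit_shift: 0.50, gamma_shift: 1.099}
  CRC:     {probit_shift: 0.50, gamma_shift: 1.253}

# Standard errors attached to the truth parameters when the configured truth
# is used directly as the probabilistic-model input (diagonal covariance).
uncertainty:
  log_shape_se: 0.01
  intercept_se: 0.02
  age_se: 0.002
  coef_se: 0.03

demographics:
  # Entry population by quintile (least -> most deprived)
  male_counts:   [23784, 20109, 21388, 18315, 19671]
  female_counts: [25149, 21171, 22689, 18782, 19749]
  male_mean_age:   [51.1, 51.8, 51.5, 50.4, 49.3]
  female_mean_age: [53.1, 53.9, 53.9, 53.2, 52.2]
  age_sd: 10.0
  age_min: 18.0
  age_max: 90.0

activity:
  # Age-standardised physical-inactivity prevalence (%) by sex and quintile;
  # the band-level distribution is built around these with an age gradient.
  male_inactive_pct:   [24.2, 27.0, 28.7, 32.4, 40.7]
  female_inactive_pct: [31.9, 31.3, 33.2, 36.5, 43.5]

relative_risks:
  # Disease risk relative to the "active" category (RR_active = 1)
  DM:      {inactive: 1.90, insufficient: 1.40}
  CHD:     {inactive: 2.20, insufficient: 1.55}
  STROKE:  {inactive: 1.85, insufficient: 1.35}
  CRC:     {inactive: 1.95, insufficient: 1.40}

utilities:
  at_risk: 0.92
  DM: 0.84
  CHD: 0.80
  STROKE: 0.74
  CRC: 0.78
  depression_multiplier: 0.83
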