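# Single-class cohort: no trajectory heterogeneity. Growth-factor means are
# the published whole-sample one-class estimates; variance components are
# the package defaults. Used as the null case for class enumeration.
n_subjects: 2235
n_waves: 4
time_scores: [0.0, 1.0, 2.0, 3.0]
class_proportions: [1.0]
class_means:
  - [3.745, -0.088]
factor_cov:
  - [0.30, 0.0]
  - [0.0, 0.01]
residual_var: 0.20
censor_to_scale: false
missing_rate: 0.0
predictor_specs: []
outcome_specs: []
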