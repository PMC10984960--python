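# Full-pipeline run on a simulated cohort with reduced grids
# (desk-scale; widen the grids for a full search).
simulate:
  n_subjects: 118
  grid_shape: [24, 28, 24]
  n_sources: 5
  loading_shift: 1.24
cv:
  tuning_mode: nested
  n_inner: 3
  c_grid: [0.01, 1.0, 100.0]
  gamma_grid: [0.01, 1.0, 100.0]
  k_grid: [3, 5, 7]
feature_sets: [brain, cognition, apoe, brain+cognition, brain+apoe, ALL]
n_boot: 2000
shap:
  n_coalitions: 2048
  max_background: 100
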