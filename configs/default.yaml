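absolute_fc: false
alpha: 0.05
classifier:
  batch_size: 32
  dropout_rate: 0.25
  epochs: 200
  hidden_width: 64
  learning_rate: 0.001
  n_hidden_layers: 6
cohort:
  ar1_coefficient: 0.3
  between_weight: 0.05
  effect_multiplier: 0.85
  effect_regions:
  - 32
  - 39
  - 58
  - 68
  - 69
  - 76
  - 77
  - 89
  n_group_a: 130
  n_group_b: 156
  n_modules: 6
  n_regions: 90
  n_timepoints: 950
  noise_sd: 0.3
  seed: 0
  subject_jitter_sd: 0.02
  tr_seconds: 0.5
  weight_sd: 0.05
  within_weight: 0.3
equal_var: true
filter_enabled: false
high_hz: 0.08
k_folds: 10
low_hz: 0.01
manifest_path: null
manifest_tr_seconds: 0.5
master_seed: 0
normalization_c: 1.0
output_dir: connectrl_run
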