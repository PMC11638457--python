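schema_version: 1
seed: 0

phantom:
  n_cases: 100
  prevalence: 0.65
  grid_shape: [32, 64, 64]
  nodularity_amp: 0.10
  texture_sigma: 1.8
  spleen_ratio: 1.4
  misalign_max: 0

split:
  fraction: 0.9
  stratified: true

preprocess:
  sequences: [T1pre, T2]
  n_slices: 5

train:
  lr: 1.0e-3
  weight_decay: 1.0e-5
  batch_size: 32
  dropout: 0.3
  max_epochs: 500
  early_stop_patience: 30   # unreported; convention default
  lr_factor: 0.5            # unreported; convention default
  lr_patience: 10           # unreported; convention default
  min_lr: 1.0e-6            # unreported; convention default
  folds: 5
  image_size: 512
  base_width: 64

augment:
  enabled: true
  rotate_deg: [-10.0, 10.0]     # unreported; convention default
  zoom: [0.9, 1.1]              # unreported; convention default
  contrast_gamma: [0.8, 1.25]   # unreported; convention default
  noise_sd: 0.01                # unreported; convention default
  elastic_alpha: 8.0            # unreported; convention default
  elastic_sigma: 4.0            # unreported; convention default
  apply_prob: 0.5               # unreported; convention default

fusion:
  grid:                         # unreported; convention default
    n_estimators: [100, 300, 500]
    max_depth: [3, 5, null]
    min_samples_leaf: [1, 5]

serum:
  ast_uln: 40.0                 # unreported; convention default

eval:
  dca_thresholds: [0.05, 0.95, 19]  # start, stop, count
  calibration_bins: 10

profiles:
  ci:
    train:
      image_size: 64
      max_epochs: 60
      early_stop_patience: 8
      lr_patience: 4
    augment:
      enabled: false
    fusion:
      grid:
        n_estimators: [100, 300]
        max_depth: [3, null]
        min_samples_leaf: [1]
  parity: {}
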