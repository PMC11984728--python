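acquisition:
  e_max: 80.0
  exposure: 10.0
  flux: 300000.0
  n_projections: 1200
  noise: true
  thresholds:
  - 25.0
  - 34.0
  - 50.0
  - 60.0
  total_rotation: 1260.0
decomposition:
  preset: auto
gating:
  band:
  - 5.0
  - 12.0
metrics:
  body_mass_g: 30.0
output_dir: runs/example
phantom:
  blood_iodine: 10.0
  grid: 64
  heart_rate: 480.0
  n_phases: 10
  target_EF_lv: 50.0
  target_EF_rv: 45.0
  voxel_size: 0.125
reconstruction:
  init: fbp
  inner_iters: 6
  lam: 0.0
  max_iters: 1
  nonneg: false
  patch: 4
  reg_blend: 0.3
  svt_frac: 0.05
seed: 1
segmentation:
  closing_radius: 1
  engine: region_grow
  tolerance_frac: 0.2
statistics:
  enabled: true
  metrics:
  - EF
  - CI
verbosity: INFO
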