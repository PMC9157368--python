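# Full-scale profile (training at this scale needs accelerator-class compute).
network:
  n_points: 4096
  n_classes: 6
  k_schedule: [16, 16, 8, 8]
  level_points: [1024, 512, 256, 128]
  level_channels: [64, 128, 256, 512]
  fused_channels: 128
  embed_dim: 5
train:
  batch_size: 8
  initial_lr: 0.002
  lr_decay: 0.7
  lr_decay_every: 10
  epochs: 190
loss:
  alpha: 1.0
  beta: 1.0
  gamma: 0.001
  delta_s: 0.5
  delta_d: 1.5
  dhl_margins: [1.0, 2.0]
  dhl_max_points: 64
data:
  n_plants_per_species: 10
  reps: 10
  split_ratio: [2, 1]
  points_per_organ: [900, 1800]
inference:
  bandwidth: 0.6
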