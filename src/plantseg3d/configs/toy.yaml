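# Desk-scale profile: small clouds, narrow network, short schedule.
network:
  n_points: 512
  n_classes: 6
  k_schedule: [16, 16, 8, 8]
  level_points: [128, 64, 32, 16]
  level_channels: [16, 32, 64, 128]
  fused_channels: 32
  embed_dim: 5
train:
  batch_size: 8
  initial_lr: 0.002
  lr_decay: 0.7
  # the full-scale recipe decays every 10 epochs = ~4550 optimizer steps; a
  # 300-step toy run lies inside one decay interval when measured in steps,
  # so the toy schedule holds the learning rate constant
  lr_decay_every: 100
  epochs: 190
  max_steps: 300
loss:
  alpha: 1.0
  beta: 1.0
  gamma: 0.001
  delta_s: 0.5
  delta_d: 1.5
  dhl_margins: [1.0, 2.0]
  dhl_max_points: 64
data:
  n_plants_per_species: 3
  reps: 4
  split_ratio: [2, 1]
  points_per_organ: [300, 600]
inference:
  bandwidth: 0.6
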