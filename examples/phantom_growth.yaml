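# A phantom patient whose enhancing lesion grows 60% between scans,
# analyzed with the desk-scale protocol (64x64x16 grid, 3-level generator,
# 200 epochs; see docs/methods.md).
phantom:
  growth_factor: 1.6

train:
  epochs: 200
  critic_updates: 5
  boosted_updates: 20
  boost_first_epochs: 5
  boost_every: 100
  gen_levels: 3
  gen_base_features: 8
  critic_channels: [8, 16, 32]
  learning_rate: 1.0e-4
  batch_size: 4

augment:
  max_rotation_deg: 15.0
  max_shift_px: [4.0, 4.0, 1.0]
  noise_var_max: 0.01

rano:
  border_margin_px: 2
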