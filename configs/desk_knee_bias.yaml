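# Desk-scale knee bias-mitigation experiment: a 240-patient race-imbalanced
# phantom cohort whose Black/African-American level renders at half contrast
# (bias_delta 0.5), trained under all four strategies and audited by race.
seed: 1
output_dir: runs/desk_knee_bias
data:
  synthetic:
    distribution: {majority: 168, minority: 72}
    seed: 1
    params:
      joint: knee
      image_size: 64
      noise_sigma: 0.08
      bias_delta: 0.5
      disadvantaged_group: [race, black_african_american]
model:
  n_classes: 4
  width_multiplier: 0.125
  use_stem: false
train:
  strategies: [baseline, balanced, stratified, group_specific]
  protected_attribute: race
  epochs: 5
  batch_size: 4
  learning_rate: 0.003
  adam_betas: [0.9, 0.99]
audit:
  attributes: [race]
  metrics: [iou, dice]
  B: 1000
  alpha: 0.05
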