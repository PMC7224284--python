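# Desktop-scale pipeline configuration: a small synthetic cohort rendered at
# the classifier's patch geometry (200 px = 62.5 um, one patch per frame).
seed: 1
out_dir: out
verbosity: INFO
cohort:
  n_ad_subjects: 3
  n_healthy_subjects: 2
  stacks_per_subject: [1, 1]
  total_stacks: 5
  frames_per_stack: 10
  field_px: 200
  field_um: 62.5
flim:
  crop_px: 24       # decay cubes are sampled on a cropped field
  max_frames: 2
  bin_radius: 1
patching:
  grid: 1
training:
  hyper_grid:
    dropout_rate: [0.3]
    learning_rate: [0.05]
    momentum: [0.9]
  epochs_max: 40
  min_epochs: 20
  patience: 8
  batch_size: 16
  arch:
    n_blocks: 4
    growth: 8
    fc_units: 16
uncertainty:
  n_calls: 20
relevance:
  n_examples: 4
evaluation:
  alpha: 0.05
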