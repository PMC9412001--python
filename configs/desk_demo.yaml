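# Desk-scale end-to-end run: 10 synthetic subjects (8 train + 2 held out)
# at 64^3, depth-3 U-Net, 5 folds, 3 epochs. Mirrors
# lesionseg.config.desk_demo_config().
seed: 0
out_dir: runs/desk_demo
simulate:
  n_subjects: 8
  n_test_subjects: 2
  n_raters: 4
  rater_sensitivity: 0.9
  rater_jitter_sd: 0.5
  rater_fp_rate: 0.5
preprocess:
  cube_size: 64
  crop_margin: 2
unet:
  base_channels: 8
  depth: 3
  slice_size: 64
train:
  n_folds: 5
  max_epochs: 3
  lr_initial: 0.3
  foreground_slice_fraction: 0.5
  early_stop_patience: 10
loss:
  k_percent: 10
merge:
  kind: unanimous
match:
  min_overlap_fraction: 0.10
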