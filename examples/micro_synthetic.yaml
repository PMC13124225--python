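# Desk-scale demonstration run: micro model on noise-free synthetic scenes.
# Omitted train keys keep the published recipe defaults (SGD, weighted
# cross-entropy, plateau decay factor 0.1 / patience 20 / min-delta 1e-4).
seed: 0
output_dir: runs/micro_demo
model:
  preset: micro
train:
  epochs: 5
  initial_lr: 0.01
data:
  kind: synthetic
  n_frames: 60
  n_pseudo_videos: 4
  test_videos: [synthvid4]
  val_fraction: 0.2
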