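# Full-scale profile (640 px, 300 epochs, batch 16). Shipped for completeness;
# the desk profile is what the test suite exercises.
epochs: 300
batch_size: 16
learning_rate: 0.01
momentum: 0.937
weight_decay: 0.0005
lr_schedule: cosine
patience: 50
input_size: 640
augment:
  mosaic: 1.0
  degrees: 10
  scale: 0.5
  fliplr: 0.5
  hsv_h: 0.015
  hsv_s: 0.7
  hsv_v: 0.4
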