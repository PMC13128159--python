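# Desk profile: single-CPU runs on 128 px phantoms with the width-0.125 model.
epochs: 30
batch_size: 8
learning_rate: 0.01
momentum: 0.937
weight_decay: 0.0005
lr_schedule: cosine
patience: 50
input_size: 128
augment:
  mosaic: 1.0
  degrees: 10
  scale: 0.5
  fliplr: 0.5
  hsv_h: 0.015   # ignored for single-channel inputs
  hsv_s: 0.7     # ignored for single-channel inputs
  hsv_v: 0.4
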