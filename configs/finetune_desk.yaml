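# Post-prune fine-tune, desk profile (single phase, batch 8).
epochs: 10
batch_size: 8
learning_rate: 0.01
lr_schedule: cosine
patience: 50
input_size: 128
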