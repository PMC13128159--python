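# High-contrast, large-blob phantom family used by the desk pipeline.
image_size: 128
tumor_count_range: [1, 2]
tumor_radius_range: [10, 18]
tumor_contrast_range: [0.5, 0.9]
edge_blur_sigma: 2.0
background_texture_scale: 12.0
noise_sigma: 0.02
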