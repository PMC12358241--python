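# Desk-scale test configuration: a reduced model that trains on CPU in
# minutes. Used by the test suite and the synthetic worked example.
model:
  backbone:
    variant: tiny_conv
    stage_channels: [8, 16, 32, 64]
    input_size: [96, 96]
  decoder_width: 32
  cmkd_branch_frac: 0.5
  cmkd_attention_reduction: 2
  rsab_qk_reduction: 4
train:
  lr: 1.0e-3
  batch_size: 8
  max_epochs: 200
  max_steps: 200
  augment: false
  seed: 42
synth:
  n_images: 8
  size: [96, 96]
  seed: 7
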