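# Full default configuration (component study row: all modules enabled).
model:
  ablation: {cmkd: true, rsab: true, asim: true, rsfm: true}
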