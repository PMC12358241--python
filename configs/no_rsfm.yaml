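# Component study: RSFM disabled (concat + CBR fusion at level 1).
model:
  ablation: {cmkd: true, rsab: true, asim: true, rsfm: false}
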