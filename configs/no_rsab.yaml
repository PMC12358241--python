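# Component study: RSAB disabled (identity on f4 before CBR).
model:
  ablation: {cmkd: true, rsab: false, asim: true, rsfm: true}
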