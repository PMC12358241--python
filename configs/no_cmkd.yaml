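# Component study: CMKD disabled (CBR applies directly to f1..f3).
model:
  ablation: {cmkd: false, rsab: true, asim: true, rsfm: true}
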