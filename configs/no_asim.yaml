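# Component study: ASIM disabled (concat + CBR fusion at levels 3 and 2).
model:
  ablation: {cmkd: true, rsab: true, asim: false, rsfm: true}
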