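{
  "telomere_bp": 47356,
  "resolved_scaffolds": {
    "NW_020555794.1": 40528,
    "NW_020555815.1": 67913,
    "NW_020555816.1": 40431,
    "NW_020555860": 311923,
    "NW_020555824.1": 13259
  }
}
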