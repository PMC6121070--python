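{
  "name": "Y1",
  "descriptor_ids": ["GATS7v", "BEHp7", "E2u", "HATS4u", "H6m", "R6u+", "R8u+"],
  "coefficients": [1.188, -1.108, -7.281, 1.453, -2.647, 28.810, -46.815],
  "intercept": 12.157
}
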