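{
  "name": "Y4",
  "descriptor_ids": ["IC1", "F05[N-F]", "R4u", "Depressant-80", "HATS7m"],
  "coefficients": [3.18, -0.46, 1.47, 0.409, 3.85],
  "intercept": -7.15
}
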