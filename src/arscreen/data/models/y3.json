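{
  "name": "Y3",
  "descriptor_ids": ["IVDE", "C-009", "BLTF96"],
  "coefficients": [5.601, -1.70, 1.11],
  "intercept": 3.02
}
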