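{
  "name": "Y2",
  "descriptor_ids": ["IC5", "GATS5e", "DISPp", "HATS3u"],
  "coefficients": [-2.89, 1.01, -3.17, -12.99],
  "intercept": 27.13
}
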