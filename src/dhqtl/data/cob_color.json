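{
  "trait": "cob color",
  "classes": {"red": 141, "white": 170},
  "n_scored_lines": 311,
  "expected_ratio": [1, 1]
}
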