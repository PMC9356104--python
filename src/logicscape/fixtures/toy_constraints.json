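{
 "note": "Synthetic constraints: the two states required as attractors.",
 "attractors": {
  "blue": {"A": 0, "B": 1, "C": 1, "D": 0, "E": 1},
  "red": {"A": 1, "B": 0, "C": 1, "D": 1, "E": 1}
 },
 "media": []
}
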