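{
 "note": "Synthetic binarization stand-ins for the experimentally observed reprogramming states (partial patterns; genes omitted from a pattern are unconstrained).",
 "attractors": {
  "MEF": {"LIF": 1, "MEKERK": 1, "Oct4": 0, "Sox2": 0, "Nanog": 0, "Esrrb": 0, "Sall4": 0, "Tfcp2l1": 0, "Klf2": 0, "Klf4": 0, "Tbx3": 0, "Gbx2": 0},
  "2NG-3NG-": {"LIF": 1, "Oct4": 1, "Sall4": 1, "Tfcp2l1": 1, "Tbx3": 0, "Sox2": 0, "Nanog": 0, "Gbx2": 0},
  "iPSC": {"LIF": 1, "Stat3": 1, "Oct4": 1, "Sox2": 1, "Nanog": 1, "Esrrb": 1, "Sall4": 1, "Tfcp2l1": 1, "Klf2": 1, "Klf4": 1, "Tbx3": 1}
 },
 "media": ["LIF"]
}
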