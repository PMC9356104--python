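{
 "note": "Synthetic binarization stand-ins for the four experimentally stable media states (partial patterns).",
 "attractors": {
  "LIF+CH+PD": {
   "LIF": 1,
   "CH": 1,
   "PD": 1,
   "MEKERK": 0,
   "Tcf3": 0,
   "Stat3": 1,
   "Oct4": 1,
   "Sox2": 1,
   "Nanog": 1,
   "Klf2": 1,
   "Klf4": 1,
   "Esrrb": 1,
   "Tfcp2l1": 1
  },
  "CH+PD": {
   "LIF": 0,
   "CH": 1,
   "PD": 1,
   "MEKERK": 0,
   "Tcf3": 0,
   "Stat3": 0,
   "Oct4": 1,
   "Sox2": 1,
   "Nanog": 1,
   "Esrrb": 1
  },
  "LIF+CH": {
   "LIF": 1,
   "CH": 1,
   "PD": 0,
   "MEKERK": 1,
   "Oct4": 1,
   "Sox2": 1,
   "Nanog": 1,
   "Klf2": 1
  },
  "LIF+PD": {
   "LIF": 1,
   "CH": 0,
   "PD": 1,
   "MEKERK": 0,
   "Tcf3": 0,
   "Oct4": 1,
   "Sox2": 1,
   "Nanog": 1,
   "Klf2": 1
  }
 },
 "media": [
  "LIF",
  "CH",
  "PD"
 ]
}
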