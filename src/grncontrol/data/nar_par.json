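{
  "version": 1,
  "name": "nar_par",
  "params": {
    "D": 0.01,
    "H": 0.005,
    "H_unstable": 0.02,
    "F": 0.04,
    "X": 250.0
  }
}
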