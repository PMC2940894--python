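{
  "version": 1,
  "name": "basal_error",
  "params": {
    "F_YZ": 0.04,
    "F_ZY": 0.01,
    "D_Y": 0.01,
    "D_Z": 0.01,
    "F_0Z": 0.1,
    "F_step": 1.0
  }
}
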