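{
  "version": 1,
  "name": "kalman_demo",
  "params": {
    "F": 0.05,
    "D": 0.01,
    "h": 1.0,
    "n_steps": 1000,
    "x_mean": 200.0,
    "x_sd": 10.0,
    "y_sd": 9.0,
    "x0": 0.0,
    "P0": 10000.0
  }
}
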