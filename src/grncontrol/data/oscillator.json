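{
  "version": 1,
  "name": "oscillator",
  "nodes": [
    {"name": "araC", "degradation": 0.01, "basal": 0.0},
    {"name": "lacI", "degradation": 0.01, "basal": 0.0}
  ],
  "edges": [
    {"source": "araC", "target": "araC", "sign": "activation", "strength": 0.04},
    {"source": "lacI", "target": "lacI", "sign": "repression", "strength": 0.02},
    {"source": "araC", "target": "lacI", "sign": "activation", "strength": 0.02},
    {"source": "lacI", "target": "araC", "sign": "repression", "strength": 0.05}
  ],
  "inputs": {"araC": 1.0},
  "input_node": "araC",
  "output_node": "lacI"
}
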