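{
  "version": 1,
  "name": "six_node",
  "nodes": [
    {"name": "A", "degradation": 0.01, "basal": 0.0},
    {"name": "B", "degradation": 0.01, "basal": 0.0},
    {"name": "C", "degradation": 0.01, "basal": 0.0},
    {"name": "D", "degradation": 0.01, "basal": 0.0},
    {"name": "E", "degradation": 0.01, "basal": 0.0},
    {"name": "F", "degradation": 0.01, "basal": 0.0}
  ],
  "edges": [
    {"source": "A", "target": "B", "sign": "activation", "strength": 0.02},
    {"source": "A", "target": "C", "sign": "activation", "strength": 0.01},
    {"source": "B", "target": "C", "sign": "activation", "strength": 0.02},
    {"source": "C", "target": "D", "sign": "activation", "strength": 0.02},
    {"source": "D", "target": "E", "sign": "activation", "strength": 0.02},
    {"source": "E", "target": "F", "sign": "activation", "strength": 0.02}
  ],
  "inputs": {"A": 5.0},
  "input_node": "A",
  "output_node": "C"
}
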