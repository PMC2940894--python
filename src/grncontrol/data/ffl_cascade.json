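{
  "version": 1,
  "name": "ffl_cascade",
  "nodes": [
    {"name": "M1", "degradation": 0.01, "basal": 0.0},
    {"name": "C1", "degradation": 0.01, "basal": 0.0},
    {"name": "Z1", "degradation": 0.01, "basal": 0.0},
    {"name": "M2", "degradation": 0.01, "basal": 0.0},
    {"name": "C2", "degradation": 0.01, "basal": 0.0},
    {"name": "C3", "degradation": 0.01, "basal": 0.0}
  ],
  "edges": [
    {"source": "M1", "target": "C1", "sign": "repression", "strength": 0.015},
    {"source": "M1", "target": "Z1", "sign": "activation", "strength": 0.01},
    {"source": "Z1", "target": "M2", "sign": "activation", "strength": 0.01},
    {"source": "Z1", "target": "C2", "sign": "activation", "strength": 0.02},
    {"source": "M2", "target": "C2", "sign": "repression", "strength": 0.015},
    {"source": "Z1", "target": "C3", "sign": "activation", "strength": 0.01},
    {"source": "M2", "target": "C3", "sign": "activation", "strength": 0.01}
  ],
  "inputs": {"M1": 2.0, "C1": 4.0, "Z1": 0.2},
  "input_node": "M1",
  "output_node": "C3"
}
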