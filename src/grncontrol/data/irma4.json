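{
  "version": 1,
  "name": "irma4",
  "nodes": [
    {"name": "CBF1", "degradation": 0.04, "basal": 0.0},
    {"name": "GAL4", "degradation": 0.04, "basal": 0.0},
    {"name": "SWI5", "degradation": 0.04, "basal": 0.0},
    {"name": "ASH1", "degradation": 0.04, "basal": 0.0}
  ],
  "edges": [
    {"source": "CBF1", "target": "GAL4", "sign": "activation", "strength": 0.01},
    {"source": "GAL4", "target": "SWI5", "sign": "activation", "strength": 0.02},
    {"source": "SWI5", "target": "CBF1", "sign": "repression", "strength": 0.02},
    {"source": "SWI5", "target": "SWI5", "sign": "activation", "strength": 0.01},
    {"source": "SWI5", "target": "ASH1", "sign": "activation", "strength": 0.01},
    {"source": "ASH1", "target": "CBF1", "sign": "repression", "strength": 0.01}
  ],
  "inputs": {"CBF1": 1.0},
  "input_node": "CBF1",
  "output_node": "SWI5"
}
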