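{
  "version": 1,
  "name": "negative_feedback",
  "nodes": [
    {"name": "Y", "degradation": 0.01, "basal": 0.0},
    {"name": "Z", "degradation": 0.01, "basal": 0.0}
  ],
  "edges": [
    {"source": "Y", "target": "Z", "sign": "activation", "strength": 0.04},
    {"source": "Z", "target": "Y", "sign": "repression", "strength": 0.01}
  ],
  "inputs": {"Y": 10.0},
  "input_node": "Y",
  "output_node": "Z"
}
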