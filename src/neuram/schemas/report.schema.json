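{
  "type": "object",
  "required": ["experiment", "seed", "results"],
  "properties": {
    "experiment": {"type": "string"},
    "seed": {"type": "integer"},
    "model": {"type": "string"},
    "config": {"type": "object"},
    "results": {"type": "object"}
  }
}
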