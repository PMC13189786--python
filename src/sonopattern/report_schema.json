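{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "sonopattern report bundle",
  "type": "object",
  "required": ["qc", "mca", "lca", "selection", "meta"],
  "properties": {
    "qc": {"type": "object"},
    "mca": {"type": "object"},
    "lca": {"type": "object"},
    "selection": {"type": "object"},
    "patterns": {"type": "object"},
    "class_profile": {"type": "object"},
    "vif": {"type": "object"},
    "firth": {"type": "object"},
    "cv": {"type": "object"},
    "bootstrap": {"type": "object"},
    "risk_differences": {"type": ["array", "object"]},
    "sensitivity": {"type": "object"},
    "meta": {"type": "object"}
  }
}
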