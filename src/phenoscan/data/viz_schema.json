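{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Phenome-scan results tree",
  "description": "Hierarchical export of ranked phenome-scan results: category nodes mirror the biobank field-category tree; leaves are tested variables.",
  "type": "object",
  "required": ["alpha", "m_tests", "threshold", "tree"],
  "properties": {
    "alpha": {"type": "number"},
    "m_tests": {"type": "integer"},
    "threshold": {"type": "number"},
    "tree": {"$ref": "#/$defs/category"}
  },
  "$defs": {
    "category": {
      "type": "object",
      "required": ["category_id", "title", "children", "variables"],
      "properties": {
        "category_id": {"type": "integer"},
        "title": {"type": "string"},
        "children": {"type": "array", "items": {"$ref": "#/$defs/category"}},
        "variables": {"type": "array", "items": {"$ref": "#/$defs/variable"}}
      }
    },
    "variable": {
      "type": "object",
      "required": ["name", "p", "estimate", "data_type", "below_threshold"],
      "properties": {
        "name": {"type": "string"},
        "p": {"type": ["number", "null"]},
        "estimate": {"type": ["number", "null"]},
        "data_type": {"enum": ["CONTINUOUS", "ORDERED", "UNORDERED", "BINARY"]},
        "below_threshold": {"type": ["boolean", "null"]}
      }
    }
  }
}
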