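{
  "type": "object",
  "required": ["metric", "rule", "ranked_cells", "selection"],
  "properties": {
    "metric": {"type": "string", "enum": ["richness", "class_coverage", "ei"]},
    "rule": {"type": "object", "required": ["type"]},
    "ranked_cells": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["i", "j", "value"],
        "properties": {
          "i": {"type": "integer"},
          "j": {"type": "integer"},
          "value": {"type": "number"}
        }
      }
    },
    "selection": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["i", "j", "value"]
      }
    }
  }
}
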