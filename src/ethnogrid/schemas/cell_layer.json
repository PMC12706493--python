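{
  "type": "object",
  "required": ["type", "features"],
  "properties": {
    "type": {"type": "string", "enum": ["FeatureCollection"]},
    "features": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["type", "geometry", "properties"],
        "properties": {
          "type": {"type": "string", "enum": ["Feature"]},
          "geometry": {
            "type": "object",
            "required": ["type", "coordinates"],
            "properties": {
              "type": {"type": "string", "enum": ["Polygon"]},
              "coordinates": {"type": "array"}
            }
          },
          "properties": {
            "type": "object",
            "required": ["i", "j", "richness", "record_count", "class_coverage", "ei"],
            "properties": {
              "i": {"type": "integer"},
              "j": {"type": "integer"},
              "richness": {"type": "integer"},
              "record_count": {"type": "integer"},
              "class_coverage": {"type": "integer"},
              "ei": {"type": "number"}
            }
          }
        }
      }
    }
  }
}
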