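{
  "type": "object",
  "required": ["taxonomy", "categorical", "class_count_distribution", "disease_class_table", "occurrence_counts"],
  "properties": {
    "taxonomy": {
      "type": "object",
      "required": ["n_species", "n_families", "n_genera"],
      "properties": {
        "n_species": {"type": "integer"},
        "n_families": {"type": "integer"},
        "n_genera": {"type": "integer"}
      }
    },
    "categorical": {"type": "object"},
    "class_count_distribution": {
      "type": "object",
      "required": ["histogram", "n_1", "n_2", "n_3_or_more", "n_3", "n_more_than_3"]
    },
    "disease_class_table": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["class_code", "class_label", "n_species"]
      }
    },
    "occurrence_counts": {
      "type": "object",
      "required": ["n_input_rows", "n_accepted", "n_rejected", "n_species_observed", "n_cells"]
    }
  }
}
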