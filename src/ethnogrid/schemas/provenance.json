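{
  "type": "object",
  "required": ["package", "version", "config", "input_checksums"],
  "properties": {
    "package": {"type": "string"},
    "version": {"type": "string"},
    "config": {"type": "object"},
    "input_checksums": {"type": "object"}
  }
}
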