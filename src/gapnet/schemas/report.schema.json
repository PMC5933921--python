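{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "gapnet recipe report",
  "type": "object",
  "required": ["recipe", "preset", "seed", "package_version", "results"],
  "properties": {
    "recipe": {"type": "string"},
    "preset": {"type": "string"},
    "seed": {"type": "integer"},
    "package_version": {"type": "string"},
    "spec_hash": {"type": "string"},
    "parameters": {"type": "object"},
    "results": {"type": "object"}
  }
}
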