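{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "pericore case report",
  "type": "object",
  "required": [
    "case_id",
    "structure",
    "marker_class",
    "breakpoints",
    "segments",
    "content_min_mb",
    "content_max_mb",
    "flags",
    "refinements",
    "tool_version",
    "input_digests"
  ],
  "properties": {
    "case_id": {"type": "string"},
    "structure": {"type": "string"},
    "marker_class": {"type": "string"},
    "breakpoints": {"type": "array"},
    "segments": {"type": "array"},
    "content_min_mb": {"type": "number"},
    "content_max_mb": {"type": ["number", "null"]},
    "mosaic_fraction": {"type": ["number", "null"]},
    "mosaic_ci": {"type": ["array", "null"]},
    "flags": {"type": "array"},
    "refinements": {"type": "array"},
    "risk": {"type": ["object", "null"]},
    "tool_version": {"type": "string"},
    "input_digests": {"type": "object"}
  }
}
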