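{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "cohortflow Sankey document",
  "type": "object",
  "required": ["meta", "nodes", "links"],
  "properties": {
    "meta": {"type": "object"},
    "nodes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "window", "label", "size", "x", "y", "height", "color"],
        "properties": {
          "id": {"type": "string"},
          "window": {"type": "integer", "minimum": 0},
          "label": {"type": "string"},
          "size": {"type": "integer", "exclusiveMinimum": 0},
          "x": {"type": "number"},
          "y": {"type": "number"},
          "height": {"type": "number", "exclusiveMinimum": 0},
          "color": {"type": "string", "pattern": "^#[0-9A-Fa-f]{6}$"},
          "entropy": {"type": ["number", "null"]},
          "highlight": {"type": "integer", "minimum": 0}
        }
      }
    },
    "links": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "source", "target", "size", "colors", "z"],
        "properties": {
          "id": {"type": "string"},
          "source": {"type": "string"},
          "target": {"type": "string"},
          "size": {"type": "integer", "exclusiveMinimum": 0},
          "probability": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
          "entropy": {"type": ["number", "null"]},
          "colors": {
            "type": "array",
            "items": {"type": "string", "pattern": "^#[0-9A-Fa-f]{6}$"},
            "minItems": 2,
            "maxItems": 2
          },
          "z": {"type": "integer", "minimum": 0},
          "highlight": {"type": "integer", "minimum": 0}
        }
      }
    }
  }
}
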