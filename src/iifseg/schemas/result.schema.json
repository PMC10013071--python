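{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "iifseg per-image result",
  "oneOf": [
    {
      "type": "object",
      "required": ["substrate", "sides"],
      "properties": {
        "substrate": {"const": "split_skin"},
        "sides": {
          "type": "object",
          "required": ["roof", "floor"],
          "additionalProperties": {
            "type": "object",
            "required": ["pattern", "call", "y", "y_pos", "y_neg", "b", "n_informative"],
            "properties": {
              "pattern": {"enum": ["epidermal", "dermal"]},
              "call": {"enum": ["positive", "negative"]},
              "y": {"type": "number", "minimum": 0, "maximum": 1},
              "y_pos": {"type": "number", "minimum": 0, "maximum": 1},
              "y_neg": {"type": "number", "minimum": 0, "maximum": 1},
              "b": {"type": ["number", "null"], "minimum": 1, "maximum": 5},
              "n_informative": {"type": "integer", "minimum": 0}
            }
          }
        }
      }
    },
    {
      "type": "object",
      "required": ["substrate", "calls", "negative", "probs", "patterns"],
      "properties": {
        "substrate": {"const": "esophagus"},
        "calls": {"type": "array", "items": {"enum": ["BMZ", "intercellular"]}},
        "negative": {"type": "boolean"},
        "probs": {
          "type": "object",
          "additionalProperties": {"type": "number", "minimum": 0, "maximum": 1}
        },
        "patterns": {
          "type": "object",
          "additionalProperties": {
            "type": "object",
            "required": ["raw_intensity", "score", "region_px"],
            "properties": {
              "raw_intensity": {"type": ["number", "null"]},
              "score": {"type": ["number", "null"], "minimum": 1, "maximum": 5},
              "region_px": {"type": "integer", "minimum": 0}
            }
          }
        }
      }
    }
  ]
}
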