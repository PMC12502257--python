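{
  "title": "Assessment-framework catalog file (format_version 1)",
  "description": "Normative description of the YAML catalog dialect. The loader enforces these rules (unknown fields rejected; fractions are exact, written as 'n/d' strings or integers).",
  "type": "object",
  "required": ["format_version", "profile", "scale", "algorithms", "indicators", "functions"],
  "properties": {
    "format_version": {"type": "integer", "const": 1},
    "profile": {"type": "string", "description": "'vmra', 'who-gbt', or a custom id (which must declare 'tiers')"},
    "version": {"type": "string"},
    "tiers": {
      "type": "array",
      "items": {"type": "string"},
      "minItems": 2,
      "description": "Ordered tier ladder; the first entry is the floor and is never a designation tier."
    },
    "tier_labels": {"type": "object", "additionalProperties": {"type": "string"}},
    "scale": {
      "type": "object",
      "description": "Rating name -> exact score in [0,1]; IMPLEMENTED must be 1 and NOT_IMPLEMENTED 0. NOT_APPLICABLE is implicit and always excluded from arithmetic.",
      "additionalProperties": {"type": ["string", "integer"]}
    },
    "algorithms": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["tiers"],
        "properties": {
          "require_critical": {"type": "boolean"},
          "tiers": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["tier", "min_implemented", "max_partial", "max_not_implemented"],
              "properties": {
                "tier": {"type": "string"},
                "min_implemented": {"type": ["string", "integer"]},
                "max_partial": {"type": ["string", "integer"]},
                "max_not_implemented": {"type": ["string", "integer"]},
                "lower_tiers_full": {"type": "boolean", "default": true},
                "pooled_with_lower": {"type": "boolean", "default": false}
              },
              "additionalProperties": false
            }
          }
        },
        "additionalProperties": false
      }
    },
    "indicators": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["code", "name"],
        "properties": {"code": {"type": "string"}, "name": {"type": "string"}},
        "additionalProperties": false
      }
    },
    "functions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["code", "name", "sub_indicators"],
        "properties": {
          "code": {"type": "string"},
          "name": {"type": "string"},
          "sub_indicators": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["id", "indicator", "tier"],
              "properties": {
                "id": {"type": "string"},
                "indicator": {"type": "string"},
                "tier": {"type": "string"},
                "text": {"type": "string"},
                "critical": {"type": "boolean", "default": false},
                "mandatory": {"type": "boolean", "default": false}
              },
              "additionalProperties": false
            }
          }
        },
        "additionalProperties": false
      }
    },
    "notes": {"type": "string"}
  },
  "additionalProperties": false
}
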