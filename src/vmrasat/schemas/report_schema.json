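{
  "title": "Maturity assessment report",
  "type": "object",
  "required": ["metadata", "functions", "institution", "idp_summary"],
  "properties": {
    "metadata": {
      "type": "object",
      "required": ["agency", "date", "profile", "catalog_version", "algorithm", "tiers"],
      "properties": {
        "agency": {"type": "string"},
        "date": {"type": "string"},
        "profile": {"type": "string"},
        "catalog_version": {"type": "string"},
        "algorithm": {"type": "string"},
        "tiers": {"type": "array", "items": {"type": "string"}}
      }
    },
    "functions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["function_code", "name", "score", "applicable_count", "tally", "result"],
        "properties": {
          "function_code": {"type": "string"},
          "name": {"type": "string"},
          "score": {"type": "number_or_null"},
          "applicable_count": {"type": "integer"},
          "result": {
            "type": "object",
            "required": ["function_code", "algorithm", "achieved_tier", "qualifier", "shortfalls"],
            "properties": {
              "function_code": {"type": "string"},
              "algorithm": {"type": "string"},
              "achieved_tier": {"type": "string"},
              "qualifier": {"type": "string"},
              "shortfalls": {"type": "array", "items": {"type": "object"}}
            }
          }
        }
      }
    },
    "institution": {
      "type": "object",
      "required": ["algorithm", "institution_tier", "mandatory_failures"],
      "properties": {
        "algorithm": {"type": "string"},
        "institution_tier": {"type": "string"},
        "mandatory_failures": {"type": "array", "items": {"type": "string"}}
      }
    },
    "idp_summary": {
      "type": "object",
      "required": ["total_gaps", "blocking", "critical"],
      "properties": {
        "total_gaps": {"type": "integer"},
        "blocking": {"type": "integer"},
        "critical": {"type": "integer"}
      }
    }
  }
}
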