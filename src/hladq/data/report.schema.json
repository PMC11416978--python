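{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "hladq clinical report",
  "type": "array",
  "items": {
    "type": "object",
    "required": [
      "sample_id",
      "predisposing_alleles",
      "serological_equivalents",
      "category",
      "interpretation",
      "ruleset",
      "warnings"
    ],
    "properties": {
      "sample_id": {"type": "string"},
      "predisposing_alleles": {
        "type": "array",
        "items": {"type": "string", "pattern": "^DQ[AB]1\\*[0-9]{2,}(:[0-9]+)*$"}
      },
      "serological_equivalents": {
        "type": "object",
        "required": ["DQ2.5", "DQ2.2", "DQ8"],
        "properties": {
          "DQ2.5": {"enum": ["present", "absent"]},
          "DQ2.2": {"enum": ["present", "absent"]},
          "DQ8": {"enum": ["present", "absent"]}
        },
        "additionalProperties": false
      },
      "category": {"enum": ["ASSOCIATED", "NOT_EXCLUDED", "EXCLUDED"]},
      "interpretation": {"type": "string"},
      "ruleset": {"enum": ["CZ2015", "CZ2020", "CZ2022", "CZ2023", "UK_BSHI"]},
      "warnings": {"type": "array", "items": {"type": "string"}}
    },
    "additionalProperties": false
  }
}
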