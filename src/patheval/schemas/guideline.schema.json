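{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "patheval/guideline.schema.json",
  "title": "Guideline bundle",
  "description": "A self-contained formal classification guideline: identity, ordered conclusions, grid columns (strength levels) and rows (evidence types), evidence codes with grid-cell assignments, combining rules, and the metarule policy. A bundle may be split into three co-located documents: rules (meta, conclusions, rules, metarules), codes (codes), grid (strength_levels, evidence_types).",
  "type": "object",
  "required": ["meta", "conclusions", "strength_levels", "evidence_types", "codes", "rules", "metarules"],
  "additionalProperties": false,
  "properties": {
    "meta": {
      "type": "object",
      "required": ["id"],
      "properties": {
        "id": {"type": "string"},
        "version": {"type": "string"},
        "name": {"type": "string"},
        "description": {"type": "string"}
      }
    },
    "conclusions": {"type": "array", "items": {"type": "string"}, "minItems": 1},
    "strength_levels": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["direction", "level_id", "rank"],
        "properties": {
          "direction": {"enum": ["pathogenic", "benign"]},
          "level_id": {"type": "string"},
          "label": {"type": "string"},
          "rank": {"type": "integer"}
        }
      }
    },
    "evidence_types": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["type_id", "label"],
        "properties": {"type_id": {"type": "string"}, "label": {"type": "string"}}
      }
    },
    "codes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["code_id", "direction", "default_strength", "evidence_type"],
        "properties": {
          "code_id": {"type": "string"},
          "direction": {"enum": ["pathogenic", "benign"]},
          "default_strength": {"type": "string"},
          "evidence_type": {"type": "string"},
          "description": {"type": "string"}
        }
      }
    },
    "rules": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["rule_id", "conclusion"],
        "properties": {
          "rule_id": {"type": "string"},
          "conclusion": {"type": "string"},
          "kind": {"enum": ["threshold", "no_rule_fallback", "directional_conflict"]},
          "terms": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["direction", "strength", "min_count"],
              "properties": {
                "direction": {"enum": ["pathogenic", "benign"]},
                "strength": {"type": "string"},
                "min_count": {"type": "integer", "minimum": 0},
                "max_count": {"type": ["integer", "null"], "minimum": 0}
              }
            }
          },
          "description": {"type": "string"}
        }
      }
    },
    "metarules": {
      "type": "object",
      "required": ["precedence", "conflict_conclusion", "insufficient_conclusion"],
      "properties": {
        "precedence": {"type": "array", "items": {"type": "string"}},
        "conflict_conclusion": {"type": "string"},
        "insufficient_conclusion": {"type": "string"},
        "conflict_scope": {"enum": ["rule", "tag"]},
        "conflict_rule": {"type": ["string", "null"]},
        "insufficient_rule": {"type": ["string", "null"]}
      }
    }
  }
}
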