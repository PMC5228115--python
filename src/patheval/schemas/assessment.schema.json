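{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "patheval/assessment.schema.json",
  "title": "Evidence document (assessment record)",
  "description": "Complete pathogenicity assessment record for one variant under one guideline. The allele identifier is an opaque string (canonical registry id and/or HGVS expression); no patient-identifying fields exist. Unknown extra fields are preserved on round-trip.",
  "type": "object",
  "required": ["allele"],
  "properties": {
    "allele": {"type": "string", "description": "Opaque allele key, e.g. CA021883 or NM_000169.2:c.639+919G>A"},
    "condition": {"type": "string"},
    "mode_of_inheritance": {"type": "string"},
    "guideline": {"type": "string", "description": "Guideline id (packaged) or path"},
    "tags": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["code"],
        "properties": {
          "code": {"type": "string"},
          "strength": {"type": ["string", "null"], "description": "Applied strength level_id; absent = the code's default"},
          "summary": {"type": ["string", "null"]},
          "links": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["url"],
              "properties": {"url": {"type": "string"}, "comment": {"type": ["string", "null"]}}
            }
          }
        }
      }
    },
    "stated_conclusion": {"type": ["string", "null"]},
    "curator": {"type": ["string", "null"]},
    "timestamps": {
      "type": "object",
      "properties": {"created": {"type": ["string", "null"]}, "modified": {"type": ["string", "null"]}}
    }
  }
}
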