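{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Portal participant payload",
  "type": "object",
  "required": [
    "sample_id",
    "absolute_risk_10y",
    "risk_category",
    "prs_z",
    "prs_population_percentile",
    "average_risk_same_age",
    "doctors_note",
    "scv_notes",
    "basis"
  ],
  "properties": {
    "sample_id": {"type": "string"},
    "absolute_risk_10y": {"type": "number", "minimum": 0, "maximum": 1},
    "risk_category": {"enum": ["low", "increased", "high", "very_high"]},
    "prs_z": {"type": "number"},
    "prs_population_percentile": {
      "type": "number",
      "exclusiveMinimum": 0,
      "exclusiveMaximum": 100
    },
    "average_risk_same_age": {"type": "number", "minimum": 0, "maximum": 1},
    "risk_at_60": {
      "description": "Present (non-null) exactly when the participant is at most 50 years old",
      "type": ["number", "null"],
      "minimum": 0,
      "maximum": 1
    },
    "doctors_note": {
      "type": "object",
      "required": [
        "recommendation",
        "template_id",
        "includes_prevalent_disease_disclaimer"
      ],
      "properties": {
        "recommendation": {
          "enum": [
            "lifestyle_only",
            "encouraged_to_see_physician",
            "recommended_to_see_physician"
          ]
        },
        "template_id": {"type": "string"},
        "includes_prevalent_disease_disclaimer": {"type": "boolean"}
      }
    },
    "scv_notes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["scv_id", "status", "action"],
        "properties": {
          "scv_id": {"type": "string"},
          "status": {
            "enum": ["non_carrier", "heterozygote", "homozygote", "no_call"]
          },
          "action": {
            "enum": [
              "none",
              "mention_to_physician_VTE",
              "mention_if_statin_planned",
              "personal_contact"
            ]
          }
        }
      }
    },
    "basis": {"enum": ["with_prs", "traditional_only"]}
  }
}
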