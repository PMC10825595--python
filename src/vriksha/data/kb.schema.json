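{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/vriksha/kb.schema.json",
  "title": "Vriksha knowledge-base document",
  "description": "Declarative knowledge base for the plant-disorder diagnostic shell: disorders (conjunctive symptom rules), symptom questions, and treatments. Array order of `disorders` is semantically significant (hypothesis order).",
  "type": "object",
  "required": ["schema_version", "symptoms", "disorders", "treatments"],
  "properties": {
    "schema_version": {"type": "string"},
    "symptoms": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "question_text"],
        "properties": {
          "id": {"type": "string", "pattern": "^[a-z][a-z0-9_]*$"},
          "question_text": {"type": "string", "pattern": "\\?$"},
          "label": {"type": "string"}
        },
        "additionalProperties": false
      }
    },
    "disorders": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name", "category", "subcategory", "symptom_ids"],
        "properties": {
          "id": {"type": "string", "pattern": "^[a-z][a-z0-9_]*$"},
          "name": {"type": "string"},
          "category": {"enum": ["internal", "external"]},
          "subcategory": {"enum": ["vata", "pitta", "kapha", "insects", "cold", "wind", "sun", "general"]},
          "description": {"type": "string"},
          "curated": {"type": "boolean"},
          "symptom_ids": {"type": "array", "items": {"type": "string"}, "minItems": 1, "uniqueItems": true},
          "treatment_ids": {"type": "array", "items": {"type": "string"}}
        },
        "additionalProperties": false
      }
    },
    "treatments": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "description"],
        "properties": {
          "id": {"type": "string", "pattern": "^[a-z][a-z0-9_]*$"},
          "description": {"type": "string"},
          "ingredients": {"type": "array", "items": {"type": "string"}},
          "source_note": {"type": "string"}
        },
        "additionalProperties": false
      }
    }
  },
  "additionalProperties": false
}
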