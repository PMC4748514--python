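{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Exergame game description document",
  "description": "YAML/JSON document mirroring the GameDescription record. Metric entries give either a full 'iri' or a 'local_name' minted in http://purl.org/net/exergame/metric#.",
  "type": "object",
  "required": ["iri", "label", "metrics"],
  "properties": {
    "iri": {"type": "string", "format": "iri"},
    "label": {"type": "string", "minLength": 1},
    "metrics": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "properties": {
          "iri": {"type": "string", "format": "iri"},
          "local_name": {"type": "string", "pattern": "^[A-Za-z_][A-Za-z0-9_.\\-]*$"},
          "label": {"type": "string"},
          "concept": {"type": "string", "format": "iri"},
          "unit": {"type": "string", "format": "iri"}
        },
        "anyOf": [{"required": ["iri"]}, {"required": ["local_name"]}]
      }
    },
    "controllers": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["iri"],
        "properties": {
          "iri": {"type": "string", "format": "iri"},
          "label": {"type": "string"},
          "same_as": {"type": "string", "format": "iri"}
        }
      }
    },
    "presentation_hardware": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["iri"],
        "properties": {
          "iri": {"type": "string", "format": "iri"},
          "label": {"type": "string"}
        }
      }
    },
    "exercise": {
      "type": "object",
      "required": ["iri"],
      "properties": {
        "iri": {"type": "string", "format": "iri"},
        "label": {"type": "string"},
        "muscles": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["iri"],
            "properties": {
              "iri": {"type": "string", "format": "iri"},
              "source": {"enum": ["ope", "ncit_subclass"]}
            }
          }
        },
        "equipment": {"type": "array", "items": {"type": "string"}},
        "benefits": {"type": "array", "items": {"type": "string"}}
      }
    },
    "goals": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["kind", "text"],
        "properties": {
          "kind": {"enum": ["game_goal", "exercise_goal"]},
          "text": {"type": "string"}
        }
      }
    }
  }
}
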