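{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "vacause case-definition configuration",
  "description": "Published contract for case-definition config files. The package validates this structure in code (with located error messages); this document is the normative description of the format.",
  "type": "object",
  "properties": {
    "extends_builtin": {
      "type": "boolean",
      "default": true,
      "description": "When true, causes not mentioned here keep their builtin definitions."
    },
    "definitions": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["strata", "predicate"],
        "properties": {
          "strata": {
            "type": "array",
            "minItems": 1,
            "items": {"enum": ["neonate_0_27d", "child_1_59m"]}
          },
          "predicate": {"$ref": "#/$defs/predicate"}
        },
        "additionalProperties": false
      }
    }
  },
  "additionalProperties": false,
  "$defs": {
    "predicate": {
      "type": "object",
      "minProperties": 1,
      "maxProperties": 1,
      "properties": {
        "all_of": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/predicate"}},
        "any_of": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/predicate"}},
        "none_of": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/predicate"}},
        "item_equals": {
          "type": "object",
          "required": ["item"],
          "properties": {"item": {"type": "string"}, "value": {}},
          "additionalProperties": false
        },
        "item_at_least": {
          "type": "object",
          "required": ["item", "count"],
          "properties": {"item": {"type": "string"}, "count": {"type": "integer", "minimum": 0}},
          "additionalProperties": false
        },
        "duration_in_days": {
          "type": "object",
          "required": ["item", "min"],
          "properties": {
            "item": {"type": "string"},
            "min": {"type": "integer", "minimum": 0},
            "max": {"type": ["integer", "null"], "minimum": 0}
          },
          "additionalProperties": false,
          "description": "Closed interval [min, max] in whole days; max null means unbounded."
        }
      },
      "additionalProperties": false
    }
  }
}
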