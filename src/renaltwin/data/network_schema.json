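{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "renaltwin arterial network file",
  "type": "object",
  "required": ["vessels", "inlet"],
  "properties": {
    "vessels": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["id", "length_mm", "radius_mm", "wall_thickness_mm", "youngs_modulus_kPa"],
        "properties": {
          "id": {"type": "string"},
          "name": {"type": "string"},
          "parent": {"type": ["string", "null"]},
          "length_mm": {"type": "number", "exclusiveMinimum": 0},
          "radius_mm": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 50},
          "wall_thickness_mm": {"type": "number", "exclusiveMinimum": 0},
          "youngs_modulus_kPa": {"type": "number", "exclusiveMinimum": 0},
          "group": {"enum": ["systemic", "renal_left", "renal_right"]},
          "generation": {"enum": ["main", "segmental", "interlobar", "arcuate"]}
        },
        "additionalProperties": false
      }
    },
    "terminals": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["vessel"],
        "properties": {
          "vessel": {"type": "string"},
          "R1": {"type": "number", "exclusiveMinimum": 0},
          "R2": {"type": "number", "exclusiveMinimum": 0},
          "C": {"type": "number", "exclusiveMinimum": 0},
          "microvascular_bed": {
            "type": "object",
            "required": ["interlobular_resistance", "nephron"],
            "properties": {
              "interlobular_resistance": {"type": "number", "exclusiveMinimum": 0},
              "nephron": {
                "type": "object",
                "additionalProperties": {"type": "number", "exclusiveMinimum": 0}
              },
              "n_interlobular_per_arcuate": {"type": "integer", "minimum": 1},
              "n_nephrons_per_interlobular": {"type": "integer", "minimum": 1},
              "surviving_fraction": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
              "compliance": {"type": "number", "exclusiveMinimum": 0}
            }
          }
        }
      }
    },
    "inlet": {
      "type": "object",
      "required": ["vessel"],
      "properties": {
        "vessel": {"type": "string"},
        "waveform_ref": {"type": "string"}
      }
    }
  }
}
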