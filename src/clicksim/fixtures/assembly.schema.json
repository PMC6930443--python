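{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Click assembly config",
  "type": "object",
  "required": ["populations"],
  "additionalProperties": false,
  "properties": {
    "_comment": {"type": "string"},
    "populations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id"],
        "properties": {
          "id": {"type": "string"},
          "lineage": {"type": "string"},
          "stage": {"enum": ["young", "mature"]},
          "growth_rate": {"type": "number", "minimum": 0},
          "death_rate": {"type": "number", "minimum": 0},
          "help_coefficient": {"type": "number", "minimum": 0},
          "initial_abundance": {"type": "number", "minimum": 0, "maximum": 1}
        }
      }
    },
    "kill_edges": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["killer", "victim"],
        "properties": {
          "killer": {"type": "string"},
          "victim": {"type": "string"},
          "kill_rate": {"type": "number", "minimum": 0},
          "mechanism": {"type": "string"}
        }
      }
    },
    "maturation_edges": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["source", "target"],
        "properties": {
          "source": {"type": "string"},
          "target": {"type": "string"},
          "rate": {"type": "number", "minimum": 0}
        }
      }
    },
    "bystander_inputs": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["target"],
        "properties": {
          "target": {"type": "string"},
          "help_level": {"type": "number", "minimum": 0}
        }
      }
    },
    "carrying_capacity": {"type": "number", "exclusiveMinimum": 0}
  }
}
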