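{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "clicksim run config",
  "type": "object",
  "required": ["assembly"],
  "additionalProperties": false,
  "properties": {
    "_comment": {"type": "string"},
    "assembly": {
      "description": "inline assembly object, a file path, or {'fixture': name, 'overrides': {...}}",
      "type": ["object", "string"]
    },
    "backend": {"enum": ["ode", "ca"]},
    "ode": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "absolute_tolerance": {"type": "number", "exclusiveMinimum": 0},
        "relative_tolerance": {"type": "number", "exclusiveMinimum": 0},
        "t_end": {"type": "number", "exclusiveMinimum": 0},
        "n_samples": {"type": "integer", "minimum": 2},
        "extinction_threshold": {"type": "number", "minimum": 0}
      }
    },
    "ca": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "width": {"type": "integer", "minimum": 4},
        "height": {"type": "integer", "minimum": 4},
        "sweeps": {"type": "integer", "minimum": 1},
        "densities": {"type": "object"},
        "dt": {"type": "number", "exclusiveMinimum": 0},
        "max_prob": {"type": "number", "exclusiveMinimum": 0, "maximum": 1}
      }
    },
    "scan": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "h_grid": {"type": "array", "items": {"type": "number", "minimum": 0}},
        "transition_h": {"type": "number", "minimum": 0},
        "stable_low_h": {"type": "number", "minimum": 0},
        "stable_high_h": {"type": "number", "minimum": 0},
        "bistable_h": {"type": "number", "minimum": 0},
        "lag": {"type": "integer", "minimum": 1},
        "n_inits": {"type": "integer", "minimum": 2}
      }
    },
    "seed": {"type": "integer"},
    "outdir": {"type": "string"}
  }
}
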