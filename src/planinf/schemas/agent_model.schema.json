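{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "planinf agent model config",
  "description": "One hierarchical level's categorical generative model. Likelihood arrays are indexed [outcome][state] with state columns normalised; transition arrays are indexed [action][next][current] with current-state columns normalised.",
  "type": "object",
  "required": [
    "states", "outcomes", "actions", "likelihood", "transitions",
    "preferences", "initial_states", "habits", "precision_grid",
    "precision_prior", "policies"
  ],
  "additionalProperties": false,
  "properties": {
    "states": {"type": "integer", "minimum": 1},
    "outcomes": {"type": "integer", "minimum": 1},
    "actions": {"type": "integer", "minimum": 1},
    "likelihood": {
      "type": "array",
      "items": {"type": "array", "items": {"type": "number", "minimum": 0}}
    },
    "likelihood_counts": {
      "type": ["array", "null"],
      "items": {"type": "array", "items": {"type": "number", "exclusiveMinimum": 0}}
    },
    "likelihood_frozen": {
      "type": ["array", "null"],
      "items": {"type": "array", "items": {"type": "boolean"}}
    },
    "transitions": {
      "type": "array",
      "items": {
        "type": "array",
        "items": {"type": "array", "items": {"type": "number", "minimum": 0}}
      }
    },
    "preferences": {
      "type": "array",
      "items": {"type": "number"},
      "description": "Unnormalised log-preferences over outcomes, ln P(o|C) up to an additive constant."
    },
    "initial_states": {
      "type": "array",
      "items": {"type": "number", "minimum": 0}
    },
    "habits": {
      "type": "array",
      "items": {"type": "array", "items": {"type": "number"}},
      "description": "Context x policy habit potentials E(pi, context)."
    },
    "precision_grid": {
      "type": "array",
      "items": {"type": "number", "exclusiveMinimum": 0},
      "description": "Strictly increasing support for the precision (beta) belief."
    },
    "precision_prior": {
      "type": "array",
      "items": {"type": "number", "minimum": 0}
    },
    "policies": {
      "type": "array",
      "minItems": 1,
      "items": {"type": "array", "items": {"type": "integer", "minimum": 0}},
      "description": "Fixed-length action sequences; all must share one horizon."
    }
  }
}
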