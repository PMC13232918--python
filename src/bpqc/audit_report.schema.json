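{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "bpqc audit report",
  "description": "JSON audit report emitted by bpqc.run_audit / `bpqc audit`. Undefined numeric quantities (empty strata, unbounded CI limits) are serialized as null, never NaN.",
  "type": "object",
  "required": ["provenance", "validation", "averaging", "differences", "digit_preference", "spike_artifact", "threshold_behavior"],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["package", "version", "config"],
      "properties": {
        "package": {"const": "bpqc"},
        "version": {"type": "string"},
        "input_path": {"type": ["string", "null"]},
        "seed": {"type": ["integer", "null"]},
        "config": {"type": "object"}
      }
    },
    "validation": {
      "type": "object",
      "required": ["n_visits_in", "n_visits_kept", "n_visits_dropped", "dropped", "protocol_violations"],
      "properties": {
        "n_visits_in": {"type": "integer", "minimum": 0},
        "n_visits_kept": {"type": "integer", "minimum": 0},
        "n_visits_dropped": {"type": "integer", "minimum": 0},
        "dropped": {"type": "object", "additionalProperties": {"type": "integer"}},
        "protocol_violations": {"type": "integer", "minimum": 0}
      }
    },
    "averaging": {
      "type": "object",
      "properties": {
        "n_visits": {"type": "integer"},
        "triplicate_fraction": {"type": ["number", "null"]},
        "protocol_violations": {"type": "integer"}
      }
    },
    "differences": {
      "type": "object",
      "properties": {
        "entries": {
          "type": "object",
          "additionalProperties": {
            "oneOf": [
              {"type": "null"},
              {
                "type": "object",
                "required": ["median", "q25", "q75", "n"],
                "properties": {
                  "median": {"type": "number"},
                  "q25": {"type": "number"},
                  "q75": {"type": "number"},
                  "n": {"type": "integer"}
                }
              }
            ]
          }
        }
      }
    },
    "digit_preference": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["n", "count_per_digit", "prop0", "prop5", "p0", "p5", "expected", "alpha"],
        "properties": {
          "n": {"type": "integer"},
          "count_per_digit": {"type": "object", "additionalProperties": {"type": "integer"}},
          "prop0": {"type": ["number", "null"]},
          "prop5": {"type": ["number", "null"]},
          "z0": {"type": ["number", "null"]},
          "p0": {"type": ["number", "null"]},
          "z5": {"type": ["number", "null"]},
          "p5": {"type": ["number", "null"]},
          "expected": {"type": "number"},
          "alpha": {"type": "number"},
          "significant0": {"type": "boolean"},
          "significant5": {"type": "boolean"},
          "half_policy": {"type": "string"}
        }
      }
    },
    "spike_artifact": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "properties": {
          "target": {"type": "integer"},
          "k_raw": {"type": "integer"},
          "n_raw": {"type": "integer"},
          "k_avg": {"type": "integer"},
          "n_avg": {"type": "integer"},
          "prop_raw": {"type": ["number", "null"]},
          "prop_avg": {"type": ["number", "null"]},
          "fisher_p": {"type": ["number", "null"]},
          "rr": {"type": ["number", "null"]},
          "ci_low": {"type": ["number", "null"]},
          "ci_high": {"type": ["number", "null"]},
          "level": {"type": "number"},
          "error": {"type": "string"}
        }
      }
    },
    "threshold_behavior": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "properties": {
          "threshold": {"type": "integer"},
          "lrt_stat": {"type": ["number", "null"]},
          "df": {"type": "integer"},
          "p_value": {"type": ["number", "null"]},
          "direction": {"enum": ["preference", "avoidance", "none", "undefined"]},
          "alpha": {"type": "number"},
          "window_halfwidth": {"type": "integer"},
          "error": {"type": "string"}
        }
      }
    }
  }
}
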