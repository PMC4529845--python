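{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Transsylvian trajectory analysis report",
  "type": "object",
  "required": [
    "provenance",
    "n_trajectories",
    "summaries",
    "paired_tests",
    "correlations",
    "headline_correlation",
    "parallelism",
    "chpc",
    "simulation"
  ],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["package", "version", "seed", "config", "landmark_source"],
      "properties": {
        "package": {"type": "string"},
        "version": {"type": "string"},
        "seed": {"type": "integer"},
        "config": {"type": "object"},
        "landmark_source": {"type": "object"}
      }
    },
    "n_trajectories": {"type": "integer"},
    "summaries": {
      "type": "object",
      "required": ["theta_a", "theta_c", "sphenoid_angle"],
      "properties": {
        "theta_a": {"$comment": "per-group summary", "type": "object"},
        "theta_c": {"type": "object"},
        "sphenoid_angle": {"type": "object"}
      }
    },
    "paired_tests": {"type": "object"},
    "correlations": {
      "type": "object",
      "required": ["pearson", "spearman"],
      "properties": {
        "pearson": {
          "type": "object",
          "required": ["method", "r", "p_value", "n"],
          "properties": {
            "method": {"type": "string"},
            "r": {"type": "number"},
            "p_value": {"type": "number"},
            "n": {"type": "integer"}
          }
        },
        "spearman": {"type": "object"}
      }
    },
    "headline_correlation": {"type": "string"},
    "parallelism": {
      "type": "object",
      "required": ["n_within", "n_total", "proportion", "tolerance", "mean_offset"],
      "properties": {
        "n_within": {"type": "integer"},
        "n_total": {"type": "integer"},
        "proportion": {"type": "number"},
        "tolerance": {"type": "number"},
        "mean_offset": {"type": "number"}
      }
    },
    "chpc": {
      "type": "object",
      "required": [
        "acpc_mean_vector_angles",
        "transform_then_average",
        "average_then_transform"
      ]
    },
    "simulation": {
      "type": ["object", "null"],
      "properties": {
        "vector": {"type": "object"},
        "n_entered": {"type": "integer"},
        "n_total": {"type": "integer"},
        "results": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["subject_id", "side", "entered"],
            "properties": {
              "subject_id": {"type": "string"},
              "side": {"type": "string"},
              "entered": {"type": "boolean"},
              "entry_distance_mm": {"type": ["number", "null"]}
            }
          }
        }
      }
    }
  }
}
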