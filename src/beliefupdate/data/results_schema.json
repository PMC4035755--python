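{
  "type": "object",
  "required": ["seed", "n_participants", "anova", "summaries_path"],
  "properties": {
    "seed": {"type": "integer"},
    "n_participants": {"type": "integer"},
    "summaries_path": {"type": "string"},
    "anova": {
      "type": "object",
      "required": ["n", "valence", "age", "interaction"],
      "properties": {
        "n": {"type": "integer"},
        "valence": {"$ref_like": "stat"},
        "age": {"$ref_like": "stat"},
        "interaction": {
          "type": "object",
          "required": ["name", "statistic", "df", "p", "tails"],
          "properties": {
            "name": {"type": "string"},
            "statistic": {"type": "number"},
            "df": {"type": "array", "items": {"type": "number"}},
            "p": {"type": "number"},
            "tails": {"type": "string"}
          }
        }
      }
    },
    "ancova": {
      "type": "object",
      "required": ["name", "statistic", "df", "p", "tails"],
      "properties": {
        "statistic": {"type": "number"},
        "df": {"type": "array", "items": {"type": "number"}},
        "p": {"type": "number"}
      }
    },
    "roi": {
      "type": "object",
      "required": ["alpha", "primary", "cross_group", "within_group"],
      "properties": {
        "alpha": {"type": "number"}
      }
    }
  }
}
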