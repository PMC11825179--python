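{
  "type": "object",
  "required": ["seed", "version", "parameters", "filters"],
  "properties": {
    "seed": {"type": "integer"},
    "version": {"type": "string"},
    "parameters": {"type": "object"},
    "filters": {
      "type": "object",
      "required": ["sites_in", "sites_out"],
      "properties": {
        "sites_in": {"type": "integer"},
        "sites_out": {"type": "integer"}
      }
    },
    "roh": {
      "type": "object",
      "required": ["per_population", "fraction_below_1mb", "froh_per_sample"],
      "properties": {
        "fraction_below_1mb": {"type": "number"},
        "froh_per_sample": {"type": "object"},
        "per_population": {"type": "array", "items": {"type": "object"}}
      }
    },
    "diversity": {
      "type": "object",
      "required": ["pi", "het_per_sample"],
      "properties": {
        "pi": {"type": "object"},
        "het_per_sample": {"type": "object"}
      }
    },
    "load": {
      "type": "object",
      "required": ["n_polarized", "per_population", "hom_ratio"],
      "properties": {
        "n_polarized": {"type": "integer"},
        "per_population": {"type": "array", "items": {"type": "object"}},
        "hom_ratio": {"type": "object"}
      }
    },
    "purging": {
      "type": "object",
      "required": ["rohf", "rxy"],
      "properties": {
        "rohf": {"type": "array", "items": {"type": "object"}},
        "rxy": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["x", "y", "category", "r"],
            "properties": {
              "x": {"type": "string"},
              "y": {"type": "string"},
              "category": {"type": "string"},
              "r": {"type": "number"},
              "se": {"type": "number"}
            }
          }
        },
        "gerp": {"type": "object"}
      }
    },
    "sfs": {"type": "object"}
  }
}
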