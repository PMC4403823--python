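{
  "type": "object",
  "required": ["provenance", "errors", "binding_params", "transport", "circulation", "display"],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["config_hash", "seed", "n_boot"],
      "properties": {
        "config_hash": {"type": "string"},
        "seed": {"type": "number"},
        "n_boot": {"type": "number"}
      }
    },
    "errors": {"type": "array", "items": {"type": "string"}},
    "binding_params": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["species", "temperature", "p50_kpa", "bohr", "cooperativity", "capacity_mmol_l"],
        "properties": {
          "species": {"type": "string"},
          "temperature": {"type": "number"},
          "venous_ph": {"type": "number"},
          "p50_kpa": {"type": "number"},
          "bohr": {"type": "number"},
          "cooperativity": {"type": "number"},
          "capacity_mmol_l": {"type": "number"},
          "hc_mg_ml": {"type": "number"}
        }
      }
    },
    "transport": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["species", "temperature", "venous_po2_kpa", "s_arterial", "s_venous", "bound_release", "total_release"],
        "properties": {
          "species": {"type": "string"},
          "temperature": {"type": "number"},
          "venous_po2_kpa": {"type": "number"},
          "s_arterial": {"type": "number"},
          "s_venous": {"type": "number"},
          "bound_release": {"type": "number"},
          "total_release": {"type": "number"}
        }
      }
    },
    "circulation": {"type": "array"},
    "display": {"type": "object"}
  }
}
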