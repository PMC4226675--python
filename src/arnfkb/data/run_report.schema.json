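{
  "type": "object",
  "required": ["config", "config_hash", "seed", "version", "stages", "complete"],
  "properties": {
    "config": {"type": "object"},
    "config_hash": {"type": "string"},
    "seed": {"type": "integer"},
    "version": {"type": "string"},
    "complete": {"type": "boolean"},
    "stages": {
      "type": "object",
      "required": [
        "chip_qc",
        "signature_scoring",
        "enrichment_ar_contrast",
        "derive_repressed_targets",
        "enrichment_gsk3_contrast",
        "survival"
      ],
      "properties": {
        "chip_qc": {"type": "object", "required": ["discarded"]},
        "signature_scoring": {"type": "object", "required": ["group_sizes", "rule"]},
        "enrichment_ar_contrast": {
          "type": "object",
          "required": ["set_name", "es", "p_nominal", "n_permutations"]
        },
        "derive_repressed_targets": {"type": "object", "required": ["name", "n_genes", "genes"]},
        "enrichment_gsk3_contrast": {
          "type": "object",
          "required": ["set_name", "es", "p_nominal", "n_permutations", "group_sizes"]
        },
        "survival": {"type": "object", "required": ["rule", "group_sizes", "horizons"]}
      }
    }
  }
}
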