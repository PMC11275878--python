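{
  "schema_version": "1",
  "required": {
    "schema_version": {"type": "str"},
    "seed": {"type": "int"},
    "provenance": {"type": "dict"},
    "bouton_counts": {"type": "dict"},
    "gap": {"type": "dict", "nullable": true},
    "projection": {"type": "dict", "nullable": true},
    "capture": {"type": "dict"},
    "tc_profiles": {"type": "list"},
    "soma_vectors": {"type": "list"},
    "neurites": {"type": "dict"}
  }
}
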