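{
  "core": "UAAAACAUACCAGAUUUCGAUCUGGAGAGGUGAAGAAUACGACCACCUA",
  "domains": {
    "core": [4, 53],
    "stem3": [53, 57],
    "stem5": [0, 4]
  },
  "kd_is_placeholder": true,
  "kd_molar": 8e-10,
  "ligand": "tetracycline",
  "name": "tetracycline",
  "part_type": "aptamer",
  "provenance": "Tetracycline aptamer (cb32 selection lineage) with its strong GC lower stem; weakened arm variants are produced by the design machinery. Kd is a literature placeholder, user-configurable.",
  "stem3": "GGCC",
  "stem5": "GGCC",
  "stem5_variants": [
    "GGCC",
    "AUAU",
    "UAUU"
  ]
}
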