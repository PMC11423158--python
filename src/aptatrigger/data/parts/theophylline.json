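{
  "core": "AUACCAGCCGAAAGGCCCUUGGCAG",
  "domains": {
    "core": [4, 29],
    "stem3": [29, 33],
    "stem5": [0, 4]
  },
  "kd_is_placeholder": true,
  "kd_molar": 3.2e-07,
  "ligand": "theophylline",
  "name": "theophylline",
  "part_type": "aptamer",
  "provenance": "Theophylline aptamer core (TCT8-4 selection lineage); lower-stem arms follow the engineered variant series with 5' arms GGUG (A1), UAUG (A2) and UAUU. Kd is a literature placeholder, user-configurable.",
  "stem3": "CACC",
  "stem5": "GGUG",
  "stem5_variants": [
    "GGUG",
    "UAUG",
    "UAUU"
  ]
}
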