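{
  "core": "AGGAUUACC",
  "domains": {
    "core": [5, 14],
    "stem3": [14, 19],
    "stem5": [0, 5]
  },
  "kd_is_placeholder": true,
  "kd_molar": 1e-09,
  "ligand": "ms2_coat_protein",
  "name": "ms2_hairpin",
  "part_type": "aptamer",
  "provenance": "MS2 bacteriophage coat-protein operator hairpin (19 nt); the protein ligand binds the loop and bulged A. Kd is a literature placeholder, user-configurable.",
  "stem3": "CAUGU",
  "stem5": "ACAUG",
  "stem5_variants": [
    "ACAUG",
    "AUG",
    "UAUG"
  ]
}
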