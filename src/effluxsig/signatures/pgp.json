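{
  "transporter": "pgp",
  "members": [
    {"metabolite": "pyridoxine", "direction": "up"},
    {"metabolite": "glutamine", "direction": "up"},
    {"metabolite": "arginine", "direction": "up"},
    {"metabolite": "creatinine", "direction": "up"},
    {"metabolite": "leucine", "direction": "up"},
    {"metabolite": "methylcysteine", "direction": "up"},
    {"metabolite": "phenylalanine", "direction": "up"},
    {"metabolite": "methionine", "direction": "up"},
    {"metabolite": "threonine", "direction": "up"},
    {"metabolite": "nicotinamide", "direction": "up"},
    {"metabolite": "pantothenate", "direction": "up"}
  ],
  "provenance": {}
}
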