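{
  "transporter": "mrp2",
  "members": [
    {"metabolite": "arginine", "direction": "up"},
    {"metabolite": "S-adenosyl-L-homocysteine", "direction": "up"},
    {"metabolite": "threonine", "direction": "up"},
    {"metabolite": "serine", "direction": "up"},
    {"metabolite": "S-adenosyl-L-methionine", "direction": "up"},
    {"metabolite": "pantothenate", "direction": "up"},
    {"metabolite": "alanine", "direction": "up"},
    {"metabolite": "carnitine", "direction": "up"},
    {"metabolite": "acetylcarnitine", "direction": "down"}
  ],
  "provenance": {}
}
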