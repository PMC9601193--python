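{
  "transporter": "bcrp",
  "members": [
    {"metabolite": "glutamate", "direction": "down"},
    {"metabolite": "hypoxanthine", "direction": "down"},
    {"metabolite": "xanthine", "direction": "down"},
    {"metabolite": "pantothenate", "direction": "up"}
  ],
  "provenance": {}
}
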