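{
  "table2_printed": [
    {"id": "1", "metal": "Zn", "pKa": 8.0},
    {"id": "2", "metal": "Cu", "pKa": 7.6},
    {"id": "3", "metal": "Ni", "pKa": 6.0}
  ],
  "table3_consistent": [
    {"id": "1", "metal": "Zn", "pKa": 8.0},
    {"id": "2", "metal": "Cu", "pKa": 6.0},
    {"id": "3", "metal": "Ni", "pKa": 7.6}
  ]
}
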