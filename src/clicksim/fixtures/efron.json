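[
  {"label": "A", "faces": [4, 4, 4, 4, 0, 0]},
  {"label": "B", "faces": [3, 3, 3, 3, 3, 3]},
  {"label": "C", "faces": [6, 6, 2, 2, 2, 2]},
  {"label": "D", "faces": [5, 5, 5, 1, 1, 1]}
]
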