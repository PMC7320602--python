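{
  "e": 1,
  "p": 3,
  "comment": "Two-search bidirectional scheme: forward search covers {000,001}, backward search covers {100,010}.",
  "searches": [
    {"pi": [1, 2, 3], "L": [0, 0, 0], "U": [0, 0, 1]},
    {"pi": [3, 2, 1], "L": [0, 0, 1], "U": [0, 1, 1]}
  ]
}
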