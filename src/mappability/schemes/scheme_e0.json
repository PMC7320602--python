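{
  "e": 0,
  "p": 1,
  "comment": "Exact search: one piece, no mismatches.",
  "searches": [
    {"pi": [1], "L": [0], "U": [0]}
  ]
}
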