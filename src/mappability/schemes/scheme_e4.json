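{
  "e": 4,
  "p": 6,
  "comment": "Fallback family: partition by the first piece carrying an error; search f with zero-error prefix of length f-1.",
  "searches": [
    {"pi": [1, 2, 3, 4, 5, 6], "L": [0, 0, 0, 0, 0, 0], "U": [0, 0, 0, 0, 0, 4]},
    {"pi": [1, 2, 3, 4, 5, 6], "L": [0, 0, 0, 0, 1, 1], "U": [0, 0, 0, 0, 4, 4]},
    {"pi": [1, 2, 3, 4, 5, 6], "L": [0, 0, 0, 1, 1, 1], "U": [0, 0, 0, 4, 4, 4]},
    {"pi": [1, 2, 3, 4, 5, 6], "L": [0, 0, 1, 1, 1, 1], "U": [0, 0, 4, 4, 4, 4]},
    {"pi": [1, 2, 3, 4, 5, 6], "L": [0, 1, 1, 1, 1, 1], "U": [0, 4, 4, 4, 4, 4]},
    {"pi": [1, 2, 3, 4, 5, 6], "L": [1, 1, 1, 1, 1, 1], "U": [4, 4, 4, 4, 4, 4]}
  ]
}
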