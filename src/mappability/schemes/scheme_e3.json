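{
  "e": 3,
  "p": 5,
  "comment": "Fallback family: partition by the first piece carrying an error; search f with zero-error prefix of length f-1.",
  "searches": [
    {"pi": [1, 2, 3, 4, 5], "L": [0, 0, 0, 0, 0], "U": [0, 0, 0, 0, 3]},
    {"pi": [1, 2, 3, 4, 5], "L": [0, 0, 0, 1, 1], "U": [0, 0, 0, 3, 3]},
    {"pi": [1, 2, 3, 4, 5], "L": [0, 0, 1, 1, 1], "U": [0, 0, 3, 3, 3]},
    {"pi": [1, 2, 3, 4, 5], "L": [0, 1, 1, 1, 1], "U": [0, 3, 3, 3, 3]},
    {"pi": [1, 2, 3, 4, 5], "L": [1, 1, 1, 1, 1], "U": [3, 3, 3, 3, 3]}
  ]
}
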