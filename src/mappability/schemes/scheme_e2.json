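{
  "e": 2,
  "p": 4,
  "comment": "Published optimum three-search scheme for two mismatches. Forward covers {0010,0011,0020}, backward {2000,1100,0200,1010,0110}, bidirectional {0000,0001,0002,1000,1001,0100,0101}.",
  "searches": [
    {"pi": [1, 2, 3, 4], "L": [0, 0, 1, 1], "U": [0, 0, 2, 2]},
    {"pi": [4, 3, 2, 1], "L": [0, 0, 0, 2], "U": [0, 1, 2, 2]},
    {"pi": [3, 2, 1, 4], "L": [0, 0, 0, 0], "U": [0, 1, 1, 2]}
  ]
}
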