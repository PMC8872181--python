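{
  "name": "fig6_branch_a",
  "start": ["tRNA-Pro", "CR", "tRNA-Phe"],
  "events": [
    {"block": [0, 2], "losses": [["orig", 0]], "segment_losses": []},
    {"block": [3, 4], "losses": [["orig", 0], ["dup", 1]], "segment_losses": [1]}
  ],
  "expected_end": ["CR", "tRNA-Pro", "tRNA-Phe", "CR"]
}
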