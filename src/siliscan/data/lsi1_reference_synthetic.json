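{
  "comment": "Synthetic reference profile: constructed scaffold, not a database sequence. Positions are 1-based.",
  "sf_positions": [
    60,
    165,
    185,
    191
  ],
  "sf_expected": "GSGR",
  "npa1": [
    70,
    72
  ],
  "npa2": [
    181,
    183
  ],
  "tmd_spans": [
    [
      10,
      30
    ],
    [
      46,
      66
    ],
    [
      80,
      100
    ],
    [
      116,
      136
    ],
    [
      151,
      171
    ],
    [
      195,
      215
    ]
  ]
}
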