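{
  "species_label": "cattle",
  "region_bounds": {
    "FR1H": [1, 26],
    "CDR1H": [27, 38],
    "FR2H": [39, 55],
    "CDR2H": [56, 65],
    "FR3H": [66, 104],
    "CDR3H": [105, 117],
    "FR4H": [118, 128]
  },
  "missing_positions": [10, 31, 32, 33, 34, 60, 61, 62, 73]
}
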