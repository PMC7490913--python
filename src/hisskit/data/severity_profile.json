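{
  "0": {
    "glucose": [[70.0, 99.0]],
    "lactate": [[0.5, 2.0]],
    "ph": [[7.35, 7.45]],
    "po2": [[100.0, 120.0]]
  },
  "1": {
    "glucose": [[70.0, 99.0]],
    "lactate": [[2.0, 3.0]],
    "ph": [[7.35, 7.45]],
    "po2": [[100.0, 120.0]]
  },
  "2": {
    "glucose": [[50.0, 69.0], [100.0, 180.0]],
    "lactate": [[2.5, 4.0]],
    "ph": [[7.3, 7.4]],
    "po2": [[100.0, 120.0]]
  },
  "3": {
    "glucose": [[30.0, 60.0], [180.0, 300.0]],
    "lactate": [[3.5, 8.0]],
    "ph": [[7.2, 7.35]],
    "po2": [[70.0, 100.0]]
  },
  "4": {
    "glucose": [[20.0, 50.0], [250.0, 500.0]],
    "lactate": [[4.0, 12.0]],
    "ph": [[7.0, 7.25]],
    "po2": [[40.0, 70.0]]
  }
}
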