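[
  {
    "name": "D1",
    "rubric_weights": {"glucose": 0.93, "lactate": 1.05, "ph": 1.1, "po2": 1.07},
    "threshold_shift": {},
    "score_ceiling": 4,
    "intra_noise": 0.08
  },
  {
    "name": "D2",
    "rubric_weights": {},
    "threshold_shift": {},
    "score_ceiling": 4,
    "intra_noise": 0.08
  },
  {
    "name": "D3",
    "rubric_weights": {"glucose": 1.05, "lactate": 0.95, "potassium": 1.05},
    "threshold_shift": {"glucose": -1.9, "lactate": -0.06, "ph": 0.007, "potassium": -0.07, "po2": 1.9},
    "score_ceiling": 4,
    "intra_noise": 0.08
  },
  {
    "name": "D4",
    "rubric_weights": {"lactate": 1.025, "ph": 0.975},
    "threshold_shift": {"po2": -1.2},
    "score_ceiling": 3,
    "intra_noise": 0.08
  },
  {
    "name": "D5",
    "rubric_weights": {},
    "threshold_shift": {"glucose": 1.2, "lactate": 0.05, "ph": -0.005, "po2": -1.2},
    "score_ceiling": 4,
    "intra_noise": 0.08
  }
]
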