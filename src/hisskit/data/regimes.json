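{
  "glucose": {
    "low_max": 70.0,
    "high_min": 99.0,
    "unit": "mg/dL",
    "low_label": "hypoglycemia",
    "normal_label": "euglycemia",
    "high_label": "hyperglycemia"
  },
  "lactate": {
    "low_max": 0.5,
    "high_min": 2.0,
    "unit": "mmol/L",
    "low_label": "hypolactatemia",
    "normal_label": "eulactatemia",
    "high_label": "hyperlactatemia"
  },
  "ph": {
    "low_max": 7.35,
    "high_min": 7.45,
    "unit": "pH",
    "low_label": "acidosis",
    "normal_label": "normal",
    "high_label": "alkalosis"
  },
  "potassium": {
    "low_max": 3.5,
    "high_min": 5.5,
    "unit": "mmol/L",
    "low_label": "hypokalemia",
    "normal_label": "eukalemia",
    "high_label": "hyperkalemia"
  },
  "po2": {
    "low_max": 100.0,
    "high_min": 120.0,
    "unit": "mmHg",
    "low_label": "hypoxia",
    "normal_label": "normal",
    "high_label": "hyperoxia"
  }
}
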