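[
  {"name": "potassium", "units": "mmol/L", "rules": [
    {"lower": 3.4, "upper": 4.7}
  ]},
  {"name": "phosphate", "units": "mmol/L", "rules": [
    {"lower": 1.13, "upper": 1.78}
  ]},
  {"name": "albumin", "units": "g/L", "rules": [
    {"lower": 36, "upper": 48, "age_max": 39},
    {"lower": 36, "upper": 45, "age_min": 40, "age_max": 69},
    {"lower": 34, "upper": 45, "age_min": 70}
  ]}
]
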