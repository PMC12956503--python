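[
  {"name": "hdl_cholesterol", "units": "mmol/L", "rules": [
    {"lower": 0.8, "upper": 2.1, "sex": "male"},
    {"lower": 1.0, "upper": 2.7, "sex": "female"}
  ]},
  {"name": "ldl_cholesterol", "units": "mmol/L", "rules": [
    {"lower": 2.0, "upper": 3.5}
  ]},
  {"name": "total_cholesterol", "units": "mmol/L", "rules": [
    {"lower": 3.9, "upper": 5.5}
  ]},
  {"name": "insulin", "units": "mU/L", "rules": [
    {"lower": 2.6, "upper": 25}
  ]},
  {"name": "glucose", "units": "mmol/L", "rules": [
    {"lower": 4, "upper": 6}
  ]}
]
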