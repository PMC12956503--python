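[
  {"name": "protein", "lower": 10, "upper": 20, "recommended": 15, "units": "E%"},
  {"name": "carbohydrates", "lower": 40, "upper": 60, "recommended": 50, "units": "E%"},
  {"name": "sucrose", "lower": 0, "upper": 10, "recommended": 2, "units": "E%"},
  {"name": "fiber", "lower": 20, "upper": 55, "recommended": 30, "units": "g/d"},
  {"name": "safa", "lower": 7, "upper": 10, "recommended": 8.5, "units": "E%"},
  {"name": "mufa", "lower": 10, "upper": 20, "recommended": 15, "units": "E%"},
  {"name": "pufa", "lower": 5, "upper": 10, "recommended": 7, "units": "E%"},
  {"name": "potassium_intake", "lower": 1600, "upper": 3700, "recommended": 3500, "units": "mg/d"},
  {"name": "phosphorus", "lower": 300, "upper": 3000, "recommended": 520, "units": "mg/d"},
  {"name": "calcium", "lower": 400, "upper": 2500, "recommended": 950, "units": "mg/d"},
  {"name": "salt", "lower": 1500, "upper": 5750, "recommended": 3750, "units": "mg/d"},
  {"name": "water", "lower": 500, "upper": 2500, "recommended": 1500, "units": "ml/d"},
  {"name": "vitamin_d", "lower": 7.5, "upper": 100, "recommended": 10, "units": "ug/d"}
]
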