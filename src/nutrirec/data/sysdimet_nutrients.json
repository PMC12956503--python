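[
  {"name": "protein", "lower": 10, "upper": 20, "recommended": 15, "units": "E%"},
  {"name": "carbohydrates", "lower": 40, "upper": 60, "recommended": 50, "units": "E%"},
  {"name": "sucrose", "lower": 0, "upper": 10, "recommended": 2, "units": "E%"},
  {"name": "fiber", "lower": 20, "upper": 55, "recommended": 30, "units": "g/d"},
  {"name": "safa", "lower": 7, "upper": 10, "recommended": 8.5, "units": "E%"},
  {"name": "mufa", "lower": 10, "upper": 20, "recommended": 15, "units": "E%"},
  {"name": "pufa", "lower": 5, "upper": 10, "recommended": 7, "units": "E%"},
  {"name": "linoleic_acid", "lower": 2.5, "upper": 9, "recommended": null, "units": "E%"},
  {"name": "alpha_linolenic_acid", "lower": 0.5, "upper": 5, "recommended": null, "units": "E%"},
  {"name": "epa", "lower": 0, "upper": 2.5, "recommended": null, "units": "mg/d"},
  {"name": "dha", "lower": 0, "upper": 2.5, "recommended": null, "units": "mg/d"},
  {"name": "cholesterol", "lower": 0, "upper": 300, "recommended": null, "units": "mg/d"},
  {"name": "folate", "lower": 100, "upper": 1000, "recommended": 330, "units": "ug/d"},
  {"name": "vitamin_d", "lower": 7.5, "upper": 100, "recommended": 10, "units": "ug/d"},
  {"name": "vitamin_c", "lower": 75, "upper": 1000, "recommended": 100, "units": "mg/d"}
]
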