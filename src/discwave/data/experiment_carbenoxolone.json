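{
  "description": "Oscillating disc treated with the gap-junction blocker Carbenoxolone at t = 20 min: waves cease immediately.",
  "name": "carbenoxolone",
  "lattice": "pouch-mini",
  "duration": 3000.0,
  "schedule": [[0.0, {"extract_dose": 1.0}], [1200.0, {"carbenoxolone": true}]],
  "params": {},
  "dt": 0.02,
  "record_interval": 1.0,
  "render": {"pixel_size": 1.0, "noise_sd": 2.0},
  "analysis": {},
  "seeds": [1],
  "measure_speed": false
}
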