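{
  "description": "Oscillating disc treated with the IP3R/SOCE inhibitor 2-APB at t = 15 min.",
  "name": "2apb",
  "lattice": "pouch-mini",
  "duration": 2700.0,
  "schedule": [[0.0, {"extract_dose": 1.0}], [900.0, {"two_apb": true}]],
  "params": {},
  "dt": 0.02,
  "record_interval": 1.0,
  "render": {"pixel_size": 1.0, "noise_sd": 2.0},
  "analysis": {},
  "seeds": [1],
  "measure_speed": false
}
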