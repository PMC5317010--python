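{
  "description": "Disc cultured in PBS only: no ligand, no stochastic spikes, no calcium activity.",
  "name": "pbs",
  "lattice": "pouch-mini",
  "duration": 1800.0,
  "schedule": [[0.0, {"extract_dose": 0.0}]],
  "params": {},
  "dt": 0.02,
  "record_interval": 1.0,
  "render": {"pixel_size": 1.0, "noise_sd": 2.0},
  "analysis": {},
  "seeds": [1],
  "measure_speed": false
}
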