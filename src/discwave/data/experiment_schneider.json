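{
  "description": "Schneider's medium without extract: locally confined IP3R-independent stochastic calcium spikes, no waves.",
  "name": "schneider",
  "lattice": "pouch-mini",
  "duration": 1800.0,
  "schedule": [[0.0, {"extract_dose": 0.0}]],
  "params": {"lambda_spike": 0.0008, "j_spike": 1.5},
  "dt": 0.02,
  "record_interval": 1.0,
  "render": {"pixel_size": 1.0, "noise_sd": 2.0},
  "analysis": {},
  "seeds": [1],
  "measure_speed": false
}
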