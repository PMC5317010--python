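{
  "description": "Peripodial membrane under 5% fly extract with the pouch-calibrated model parameters; only the lattice (large squamous cells) differs.",
  "name": "peripodium",
  "lattice": "peripodium",
  "duration": 2400.0,
  "schedule": [[0.0, {"extract_dose": 1.0}]],
  "params": {},
  "dt": 0.02,
  "record_interval": 0.5,
  "render": {"pixel_size": 2.0, "noise_sd": 2.0},
  "analysis": {},
  "seeds": [1, 2, 3],
  "measure_speed": true,
  "speed_region": "peripodium"
}
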