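{
  "description": "As pouch-18C but larvae reared at 25 C: the metabolic tissue state is modeled as a single gain on ligand-driven IP3 production and store-operated entry.",
  "name": "pouch-25C",
  "lattice": "wing-disc",
  "duration": 3600.0,
  "schedule": [
    [
      0.0,
      {
        "extract_dose": 1.0
      }
    ]
  ],
  "params": {
    "v_plc": 0.0335,
    "v_soce": 0.0235,
    "d_c": 3.75,
    "region_modifiers": {
      "hinge_dorsal": {
        "v_plc": 0.75,
        "v_soce": 1.0,
        "tau_h": 2.0
      },
      "hinge_ventral": {
        "v_plc": 0.75,
        "v_soce": 1.0,
        "tau_h": 2.0
      },
      "hinge_anterior": {
        "v_plc": 0.75,
        "v_soce": 1.0,
        "tau_h": 2.0
      },
      "hinge_posterior": {
        "v_plc": 0.75,
        "v_soce": 1.0,
        "tau_h": 2.0
      }
    }
  },
  "dt": 0.02,
  "record_interval": 0.5,
  "render": {
    "pixel_size": 1.0,
    "noise_sd": 2.0
  },
  "analysis": {},
  "seeds": [
    1,
    2,
    3
  ],
  "measure_speed": true,
  "speed_region": "pouch"
}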