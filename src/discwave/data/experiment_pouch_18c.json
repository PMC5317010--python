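{
  "description": "Wing disc cultured in Schneider's medium with 5% fly extract, larvae reared at 18 C. Full disc-proper lattice; hinge regions carry reduced ligand sensitivity and slower IP3R recovery.",
  "name": "pouch-18C",
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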