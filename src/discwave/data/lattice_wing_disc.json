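{
  "description": "Columnar wing-disc layer: elliptical pouch inside an annular hinge split into four sectors. Dorsal and ventral pouch borders are folds (zero coupling); anterior and posterior borders are open corridors. Hinge cell area (18 um^2) is an assumption between the measured pouch and peripodium values. Corridor boundaries carry reduced junctional conductance.",
  "regions": [
    {
      "name": "pouch",
      "shape": {
        "type": "ellipse",
        "center": [
          0,
          0
        ],
        "semi_axes": [
          65,
          55
        ],
        "n_vertices": 96
      },
      "mean_cell_area": 4.4,
      "area_cv": 0.2
    },
    {
      "name": "hinge_dorsal",
      "shape": {
        "type": "annulus_sector",
        "center": [
          0,
          0
        ],
        "outer": [
          92,
          80
        ],
        "inner": [
          65,
          55
        ],
        "wedge": "dorsal",
        "n_vertices": 96
      },
      "mean_cell_area": 18.0,
      "area_cv": 0.2
    },
    {
      "name": "hinge_ventral",
      "shape": {
        "type": "annulus_sector",
        "center": [
          0,
          0
        ],
        "outer": [
          92,
          80
        ],
        "inner": [
          65,
          55
        ],
        "wedge": "ventral",
        "n_vertices": 96
      },
      "mean_cell_area": 18.0,
      "area_cv": 0.2
    },
    {
      "name": "hinge_anterior",
      "shape": {
        "type": "annulus_sector",
        "center": [
          0,
          0
        ],
        "outer": [
          92,
          80
        ],
        "inner": [
          65,
          55
        ],
        "wedge": "anterior",
        "n_vertices": 96
      },
      "mean_cell_area": 18.0,
      "area_cv": 0.2
    },
    {
      "name": "hinge_posterior",
      "shape": {
        "type": "annulus_sector",
        "center": [
          0,
          0
        ],
        "outer": [
          92,
          80
        ],
        "inner": [
          65,
          55
        ],
        "wedge": "posterior",
        "n_vertices": 96
      },
      "mean_cell_area": 18.0,
      "area_cv": 0.2
    }
  ],
  "fold_edges": [
    [
      "pouch",
      "hinge_dorsal"
    ],
    [
      "pouch",
      "hinge_ventral"
    ]
  ],
  "boundary_coupling": [
    [
      "pouch",
      "hinge_anterior",
      0.01
    ],
    [
      "pouch",
      "hinge_posterior",
      0.01
    ]
  ]
}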