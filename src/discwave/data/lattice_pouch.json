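{
  "description": "Pouch-only lattice at full template size (columnar cells).",
  "regions": [
    {
      "name": "pouch",
      "shape": {"type": "ellipse", "center": [0, 0], "semi_axes": [65, 55], "n_vertices": 96},
      "mean_cell_area": 4.4,
      "area_cv": 0.2
    }
  ],
  "fold_edges": []
}
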