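{
  "description": "Reduced pouch-only lattice (~500 cells) for fast pharmacology and property experiments.",
  "regions": [
    {
      "name": "pouch",
      "shape": {"type": "ellipse", "center": [0, 0], "semi_axes": [28, 24], "n_vertices": 64},
      "mean_cell_area": 4.4,
      "area_cv": 0.2
    }
  ],
  "fold_edges": []
}
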