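{
  "description": "Peripodial membrane: one elliptical sheet of large squamous cells, modeled as a separate layer with no coupling to the columnar disc proper.",
  "regions": [
    {
      "name": "peripodium",
      "shape": {"type": "ellipse", "center": [0, 0], "semi_axes": [92, 80], "n_vertices": 96},
      "mean_cell_area": 113.5,
      "area_cv": 0.2
    }
  ],
  "fold_edges": []
}
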