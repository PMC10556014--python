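{
  "_comment": "Template insole masking schemes for trimmed in-shoe layouts. All three tables are APPROXIMATIONS shipped as editable defaults: bands are fractions of the active insole extent, y posterior->anterior, x medial->lateral within each band.",
  "pedar_mask1": {
    "note": "approximation: 3-region rearfoot/midfoot/forefoot split",
    "regions": [
      {"name": "rearfoot", "y": [0.0, 0.3]},
      {"name": "midfoot", "y": [0.3, 0.55]},
      {"name": "forefoot_toes", "y": [0.55, 1.0]}
    ]
  },
  "pedar_mask2": {
    "note": "approximation: 9-region medial/lateral split scheme",
    "regions": [
      {"name": "heel_medial", "y": [0.0, 0.3], "x": [0.0, 0.5]},
      {"name": "heel_lateral", "y": [0.0, 0.3], "x": [0.5, 1.0]},
      {"name": "midfoot_medial", "y": [0.3, 0.55], "x": [0.0, 0.5]},
      {"name": "midfoot_lateral", "y": [0.3, 0.55], "x": [0.5, 1.0]},
      {"name": "forefoot_medial", "y": [0.55, 0.82], "x": [0.0, 0.35]},
      {"name": "forefoot_central", "y": [0.55, 0.82], "x": [0.35, 0.7]},
      {"name": "forefoot_lateral", "y": [0.55, 0.82], "x": [0.7, 1.0]},
      {"name": "hallux", "y": [0.82, 1.0], "x": [0.0, 0.35]},
      {"name": "lesser_toes", "y": [0.82, 1.0], "x": [0.35, 1.0]}
    ]
  },
  "pedar_mask3": {
    "note": "approximation: 10-region scheme mirroring the barefoot automask proportions",
    "regions": [
      {"name": "heel", "y": [0.0, 0.3]},
      {"name": "midfoot", "y": [0.3, 0.55]},
      {"name": "MTH1", "y": [0.55, 0.82], "x": [0.0, 0.3]},
      {"name": "MTH2", "y": [0.55, 0.82], "x": [0.3, 0.5]},
      {"name": "MTH3", "y": [0.55, 0.82], "x": [0.5, 0.675]},
      {"name": "MTH4", "y": [0.55, 0.82], "x": [0.675, 0.85]},
      {"name": "MTH5", "y": [0.55, 0.82], "x": [0.85, 1.0]},
      {"name": "hallux", "y": [0.82, 1.0], "x": [0.0, 0.35]},
      {"name": "toe2", "y": [0.82, 1.0], "x": [0.35, 0.55]},
      {"name": "toes3_5", "y": [0.82, 1.0], "x": [0.55, 1.0]}
    ]
  }
}
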