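{
  "description": "SiliGlass phantom recipe constants and synthetic-table metadata",
  "dilution_denominator": 0.13246,
  "predilution_ratio": 2272,
  "wall_loss_g": 1.0,
  "thickness_cm": 2.0,
  "sphere_index": 1.65,
  "cab_subtract_scatterer": false,
  "provenance": "synthetic band-model compilations generated by scripts/make_tables.py"
}
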