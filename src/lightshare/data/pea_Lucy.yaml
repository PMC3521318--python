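name: Lucy
leaf_type: semi-leafless
schnute:
  A: 0.00189
  B: 0.39
  y_max: 24.8
  t_max: 1565.0
maturity_dd: 1565.0
branching:
- stage_dd: 300
  range:
  - 0
  - 0
  phytomers_per_branch: []
- stage_dd: 1240
  range:
  - 0
  - 1
  phytomers_per_branch:
  - 3.0
branch_insertion:
  mode: basal
  ranks:
  - 1
  - 3
internode:
  mean_length_mm: 42.1
  multiplier:
  - - 0.0
    - 0.85
  - - 0.3
    - 1.0
  - - 0.5
    - 1.1
  - - 0.65
    - 1.15
  - - 0.8
    - 1.05
  - - 1.0
    - 0.7
stipule:
  length_knots:
  - - 0.0
    - 30.0
  - - 0.3
    - 38.0
  - - 0.6
    - 50.0
  - - 0.8
    - 50.0
  - - 1.0
    - 25.0
  inclination_knots:
  - - 0
    - 44.5
  - - 300
    - 44.5
  - - 600
    - 43.3
  - - 1240
    - 48.7
  - - 1565
    - 48.7
leaflet: null
area_contributions:
  stipules: 0.91
  stems: 0.09
growth_duration_dd: 225.0
area_scale: 1.238
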