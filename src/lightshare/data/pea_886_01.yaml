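name: 886/01
leaf_type: semi-leafless
schnute:
  A: 0.0008
  B: 0.65
  y_max: 37.6
  t_max: 1890.0
maturity_dd: 1890.0
branching:
- stage_dd: 300
  range:
  - 0
  - 0
  phytomers_per_branch: []
- stage_dd: 600
  range:
  - 0
  - 2
  phytomers_per_branch:
  - 7.4
  - 3.7
- stage_dd: 1240
  range:
  - 1
  - 3
  phytomers_per_branch:
  - 18.6
  - 14.2
  - 10.0
- stage_dd: 1560
  range:
  - 1
  - 3
  phytomers_per_branch:
  - 23.5
  - 16.9
  - 12.4
branch_insertion:
  mode: basal
  ranks:
  - 1
  - 3
internode:
  mean_length_mm: 29.0
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
    - 18.0
  - - 0.3
    - 28.0
  - - 0.6
    - 50.0
  - - 0.8
    - 50.0
  - - 1.0
    - 30.0
  inclination_knots:
  - - 0
    - 41.7
  - - 300
    - 41.7
  - - 600
    - 38.6
  - - 1240
    - 51.1
  - - 1560
    - 55.0
  - - 1890
    - 55.0
leaflet: null
area_contributions:
  stipules: 0.91
  stems: 0.09
growth_duration_dd: 150.0
area_scale: 1.575
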