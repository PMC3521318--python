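name: AOPH10
leaf_type: semi-leafless
schnute:
  A: 0.00118
  B: 0.57
  y_max: 32.9
  t_max: 1630.0
maturity_dd: 1630.0
branching:
- stage_dd: 300
  range:
  - 0
  - 1
  phytomers_per_branch:
  - 3.0
- stage_dd: 600
  range:
  - 0
  - 2
  phytomers_per_branch:
  - 9.5
  - 5.0
- stage_dd: 1240
  range:
  - 0
  - 2
  phytomers_per_branch:
  - 22.8
  - 6.0
- stage_dd: 1560
  range:
  - 0
  - 1
  phytomers_per_branch:
  - 25.7
branch_insertion:
  mode: basal
  ranks:
  - 1
  - 3
internode:
  mean_length_mm: 30.2
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
    - 37.8
  - - 300
    - 37.8
  - - 600
    - 38.7
  - - 1240
    - 49.7
  - - 1560
    - 49.8
  - - 1630
    - 49.8
leaflet: null
area_contributions:
  stipules: 0.91
  stems: 0.09
growth_duration_dd: 825.0
area_scale: 1.398
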