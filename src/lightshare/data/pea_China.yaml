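name: China
leaf_type: leafy
schnute:
  A: 0.00214
  B: 0.47
  y_max: 20.6
  t_max: 1310.0
maturity_dd: 1310.0
branching:
- stage_dd: 300
  range:
  - 0
  - 0
  phytomers_per_branch: []
- stage_dd: 600
  range:
  - 0
  - 1
  phytomers_per_branch:
  - 2.5
- stage_dd: 1240
  range:
  - 0
  - 1
  phytomers_per_branch:
  - 2.8
branch_insertion:
  mode: mid
  ranks:
  - 12
  - 14
internode:
  mean_length_mm: 56.6
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
    - 25.4
  - - 300
    - 25.4
  - - 600
    - 40.0
  - - 1240
    - 51.3
  - - 1310
    - 51.3
leaflet:
  length_knots:
  - - 0.0
    - 25.0
  - - 0.5
    - 45.0
  - - 1.0
    - 22.0
  inclination_knots:
  - - 0
    - 16.0
  - - 300
    - 16.0
  - - 600
    - 20.0
  - - 1240
    - 30.0
  - - 1310
    - 30.0
  pairs_per_node: 1
area_contributions:
  stipules: 0.47
  leaflets: 0.45
  stems: 0.08
growth_duration_dd: 300.0
area_scale: 1.179
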