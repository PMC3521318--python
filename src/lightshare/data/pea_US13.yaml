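name: US13
leaf_type: leafy
schnute:
  A: 0.00189
  B: 0.44
  y_max: 24.6
  t_max: 1445.0
maturity_dd: 1445.0
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
  - 8.0
branch_insertion:
  mode: basal
  ranks:
  - 1
  - 3
internode:
  mean_length_mm: 43.2
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
    - 39.0
  - - 300
    - 39.0
  - - 600
    - 40.3
  - - 1240
    - 60.0
  - - 1445
    - 60.0
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
    - 26.0
  - - 300
    - 26.0
  - - 600
    - 26.0
  - - 1240
    - 34.0
  - - 1445
    - 34.0
  pairs_per_node: 1
area_contributions:
  stipules: 0.46
  leaflets: 0.49
  stems: 0.05
growth_duration_dd: 225.0
area_scale: 1.359
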