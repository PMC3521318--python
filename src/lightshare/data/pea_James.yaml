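name: James
leaf_type: semi-leafless
schnute:
  A: 0.00194
  B: 0.49
  y_max: 25.6
  t_max: 1445.0
maturity_dd: 1445.0
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
  - 1
  phytomers_per_branch:
  - 5.7
- stage_dd: 1240
  range:
  - 0
  - 1
  phytomers_per_branch:
  - 6.0
branch_insertion:
  mode: basal
  ranks:
  - 1
  - 3
internode:
  mean_length_mm: 32.1
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
    - 38.0
  - - 300
    - 38.0
  - - 600
    - 39.3
  - - 1240
    - 45.2
  - - 1445
    - 45.2
leaflet: null
area_contributions:
  stipules: 0.905
  stems: 0.095
growth_duration_dd: 450.0
area_scale: 1.051
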