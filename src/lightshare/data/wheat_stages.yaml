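stages:
- stage_dd: 300.0
  lai: 0.13
  height_m: 0.113
  inclination_deg: 65.5
- stage_dd: 600.0
  lai: 0.83
  height_m: 0.16
  inclination_deg: 67.0
- stage_dd: 1240.0
  lai: 1.0
  height_m: 0.652
  inclination_deg: 64.3
- stage_dd: 1560.0
  lai: 0.46
  height_m: 0.691
  inclination_deg: 61.0
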