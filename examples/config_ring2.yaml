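# Example scenario configuration (see `ringmech.io.load_config`).
# Units are fixed: mm, N, MPa, mmHg.  Values may also be written as
# {value: ..., unit: ...} pairs, in which case the unit is checked.
units:
  length: mm
  force: N
  stress: MPa
  pressure: mmHg

ring: ring2              # preset; or spell out d_wire / D_ring / n_turns
nitinol: nitinol_37C     # 37 degC wire calibration

vessel:
  preset: aorta_labrosse_67_77
  oversize_pct: 10.0

saddle:
  string_stiffness_ref: {value: 7.41, unit: N/mm}
  string_length: 100.0
  oversize_high: 30.0
  oversize_low: 10.0
  n_cycles: 3

deploy:
  catheter_diameter: 6.9
  inner_tube_diameter: 2.0
  P_d: 80.0
  P_s: 120.0
  mu_vessel: 0.05
  mu_sheath: 0.0
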