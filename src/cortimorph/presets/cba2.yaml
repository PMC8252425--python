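name: CBA2
n_columns: 18
ohc_pitch_um: 6.8
row_spacing_um: 10.0
opc_offset_um: -7.0
opc_length_um:
- 35.0
- 1.5
voxel_pitch_nm:
- 12.0
- 12.0
- 50.0
node_spacing_um: 1.0
jitter_perp_um: 0.15
root_jitter_inplane_um: 0.3
root_jitter_outplane_um: 0.2
n_dropout:
- 3
- 3
- 3
L_OHC:
- - 23.26
  - 0.72
- - 22.79
  - 0.92
- - 23.26
  - 0.83
L_PhP:
- - 36.94
  - 1.58
- - 33.96
  - 1.67
- - 30.84
  - 1.58
L_DC:
- - 38.09
  - 1.78
- - 39.72
  - 1.41
- - 42.31
  - 1.4
alpha:
- - 52.36
  - 3.14
- - 44.73
  - 2.45
- - 35.65
  - 3.07
beta_DC:
- - 86.98
  - 1.93
- - 81.02
  - 2.03
- - 73.64
  - 1.71
beta_OHC:
- - 109.79
  - 3.07
- - 105.43
  - 2.92
- - 107.23
  - 3.35
beta_PhP_ref:
- - 61.45
  - 2.48
- - 66.58
  - 3.75
- - 75.01
  - 3.25
beta_OPC:
- 101.04
- 3.04
spans:
- 4
- 3
- 2
php_insertion_offset_um: -1.5
n_t2sgn: 10
ohc_afferent_mean:
- 2.39
- 1.97
- 2.03
ribbon_fraction:
- 0.313
- 0.389
- 0.5
row_mixing_prob: 0.125
climbing_slope:
- 0.23
- 0.07
contact_slope:
- 0.02
- 0.09
turn_height_um:
- 13.0
- 2.0
plateau_height_um:
- 36.53
- 3.0
contact_heights_um:
- - 21.39
  - 3.06
- - 17.81
  - 5.23
- - 19.73
  - 5.64
- - 23.85
  - 6.68
per_dc_abundance:
- 20.4
- 13.6
- 7.6
fiber_row_offset_um: 1.2
n_moc: 16
moc_branched_fraction: 0.243
moc_branched_synapses:
- 5.18
- 2.3
- 3
- 11
moc_unbranched_synapses:
- 2.26
- 1.0
- 1
- 4
moc_branched_rows:
- 0.423
- 0.327
- 0.25
moc_unbranched_rows:
- 0.346
- 0.346
- 0.308
moc_modal_concentration: 0.7
tc_zone_um:
- -22.0
- -14.0
basal_hint:
- 1.0
- 0.0
- 0.0
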