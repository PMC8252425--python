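name: CBA1
n_columns: 32
ohc_pitch_um: 6.8
row_spacing_um: 10.0
opc_offset_um: -7.0
opc_length_um:
- 35.0
- 1.5
voxel_pitch_nm:
- 11.0
- 11.0
- 40.0
node_spacing_um: 1.0
jitter_perp_um: 0.15
root_jitter_inplane_um: 0.3
root_jitter_outplane_um: 0.2
n_dropout:
- 3
- 2
- 3
L_OHC:
- - 22.8
  - 0.8
- - 23.45
  - 1.05
- - 24.75
  - 1.06
L_PhP:
- - 37.86
  - 2.11
- - 38.01
  - 2.9
- - 33.18
  - 1.51
L_DC:
- - 33.65
  - 2.28
- - 32.57
  - 3.18
- - 36.61
  - 1.68
alpha:
- - 45.58
  - 2.29
- - 36.09
  - 3.37
- - 30.22
  - 2.44
beta_DC:
- - 91.77
  - 3.01
- - 86.38
  - 2.98
- - 78.73
  - 3.45
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
n_t2sgn: 40
ohc_afferent_mean:
- 2.39
- 1.97
- 2.03
ribbon_fraction:
- 0.316
- 0.311
- 0.538
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
n_moc: 70
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
- 0.4
- 0.367
- 0.233
moc_unbranched_rows:
- 0.344
- 0.353
- 0.303
moc_modal_concentration: 0.7
tc_zone_um:
- -22.0
- -14.0
basal_hint:
- 1.0
- 0.0
- 0.0
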