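# Control-parameter sets (zeta) of the five selected gait cycles pi1..pi5.
# Units as printed: lengths cm, angles rad, angular rates rad/s, length
# rates cm/s.
units:
  L_stv_mid: cm
  L_stv_end: cm
  q_P_mid: rad
  q_P_end: rad
  qd_P_end: rad/s
  q_T_mid: rad
  q_T_end: rad
  qd_T_end: rad/s
  L_st_ankle_mid: cm
  L_st_ankle_end: cm
  Ld_st_ankle_end: cm/s
  L_sw_ankle_mid: cm
  L_sw_ankle_end: cm
  Ld_sw_ankle_end: cm/s
columns: [pi1, pi2, pi3, pi4, pi5]
values:
  L_stv_mid:       [79.6, 79.6, 80.0, 80.0, 80.3]
  L_stv_end:       [82.0, 82.0, 83.6, 81.1, 81.9]
  q_P_mid:         [-0.05, -0.05, -0.05, -0.05, -0.05]
  q_P_end:         [-0.05, -0.05, -0.05, -0.05, -0.05]
  qd_P_end:        [-0.15, -0.15, -0.15, -0.15, -0.15]
  q_T_mid:         [0, 0, 0, 0, 0]
  q_T_end:         [0, 0, 0, 0, 0]
  qd_T_end:        [-0.15, -0.15, -0.15, -0.15, -0.15]
  L_st_ankle_mid:  [8.6, 7.2, 5.6, 5.6, 5.6]
  L_st_ankle_end:  [9.4, 8.6, 6.2, 6.2, 6.9]
  Ld_st_ankle_end: [10, 10, 20, 20, 20]
  L_sw_ankle_mid:  [8.4, 8.4, 8.1, 8.1, 8.1]
  L_sw_ankle_end:  [7.6, 7.6, 6.2, 6.8, 6.8]
  Ld_sw_ankle_end: [0, 0, 10, 10, 10]
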