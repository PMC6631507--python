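{
  "name": "3dc",
  "n_channels": 10,
  "out_rate": 1000,
  "enob": 10,
  "full_scale_pp": 0.006,
  "analog_hp_hz": 1.0,
  "analog_lp_hz": 7000.0,
  "osr": 50,
  "cic_order": 4,
  "cic_diff_delay": 1,
  "noise_rms": 2.2e-06,
  "electrode_angles": [0, 36, 72, 108, 144, 180, 216, 252, 288, 324]
}
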