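{
  "name": "myo",
  "n_channels": 8,
  "out_rate": 200,
  "enob": 8,
  "full_scale_pp": 0.002,
  "analog_hp_hz": 5.0,
  "analog_lp_hz": null,
  "osr": null,
  "cic_order": 4,
  "cic_diff_delay": 1,
  "noise_rms": 2.2e-06,
  "electrode_angles": [
    0,
    45,
    90,
    135,
    180,
    225,
    270,
    315
  ]
}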