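seed: 20260
simulation:
  n_droplets: 20000
  alpha_mode: fixed
  alpha: 0.5
  volume_modes: [[50.0, 1.0]]
  c_p: 2.0e7
  c_b_nominal: 1.6e9
populations:
  mode: none
digitization:
  k_max: 4
  method: weights
estimation: {}
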