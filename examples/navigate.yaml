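experiment:
  protocol: navigate
  p_inf: 0.2
  Gamma_z_social: 25.0
  Gamma_z_target: 25.0
  n_trials: 25
  target_distance: 10.0
  success_radius: 0.25
n_agents: 30
duration_s: 15.0
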