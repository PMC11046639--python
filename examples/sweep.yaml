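experiment:
  protocol: sweep
  gamma_values: [10.0, 25.0, 50.0]
  lambda_values: [1.0, 1.2, 1.5]
  n_trials: 10
  t0: 5.0
n_agents: 50
duration_s: 15.0
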