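experiment:
  protocol: perturb
  n_init: 5
  n_real: 5
  n_perturbed: 1
  amplitude: 2.0
  phase_duration: 0.5
  repetitions: 2
  burn_in: 10.0
  post: 20.0
  stim_delay: 0.5
n_agents: 50
duration_s: 20.0
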