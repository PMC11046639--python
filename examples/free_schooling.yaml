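experiment: {protocol: simulate}
n_agents: 50
duration_s: 15.0
master_seed: 1
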