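# Figure-scale distance-distributed stimulation across network sizes
# (long-running).
experiment: distance_stim
seed: 0
size_grid: [100, 200, 300, 400, 500]
sigma: 5.0
gamma_S: 8.0
n_steps: 2000000
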