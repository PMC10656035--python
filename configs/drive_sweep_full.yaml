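# Figure-scale confounder-drive sweep on a 200-neuron Dale network
# (long-running).
experiment: drive_sweep
seed: 0
n_neurons: 200
gamma_ex_grid: [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
gamma_in_grid: [0.0, -1.0, -2.0, -3.0, -4.0, -5.0, -6.0, -7.0]
sigma: 5.0
gamma_S: 6.0
n_stimulated: 5
n_steps: 2000000
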