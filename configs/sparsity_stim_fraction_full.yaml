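# Figure-scale sparsity / stimulated-fraction study on 200-neuron networks
# (long-running).
experiment: sparsity_stim_fraction
seed: 0
n_neurons: 200
sparsity_grid: [0.0, 0.3, 0.6, 0.9]
stim_count_grid: [5, 20, 50, 100]
sigma: 5.0
gamma_S: 6.0
n_steps: 2000000
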