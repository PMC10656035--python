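# Figure-scale three-neuron convergence study (long-running: ~10^6 trials
# requires ~5x10^7 simulated ms; hours on one CPU).
experiment: three_neuron
seed: 0
weight_grid: [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
n_steps: 50000000
gamma_S: 5.0
n_boot: 200
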