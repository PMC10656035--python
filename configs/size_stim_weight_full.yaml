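# Figure-scale grid over size, stimulus strength and connection scale
# (480-network scale; cluster territory).
experiment: size_stim_weight_sweep
seed: 0
size_grid: [50, 100, 150, 200]
gamma_S_grid: [0.0, 2.0, 4.0, 6.0, 8.0]
sigma_grid: [2.0, 5.0, 10.0]
n_stimulated: 5
n_steps: 2000000
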