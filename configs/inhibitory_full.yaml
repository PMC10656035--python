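# Figure-scale inhibitory-stimulation study on a 120-neuron Dale network
# (long-running).
experiment: inhibitory
seed: 0
n_neurons: 120
sigma: 5.0
gamma_S: 3.0
n_stimulated: 5
n_steps: 2000000
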