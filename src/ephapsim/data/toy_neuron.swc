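# toy_neuron.swc — synthetic hand-built morphology (not a database neuron)
# soma + bifurcating dendrite + short axon; columns: id type x y z radius parent
1 1 0 0 0 8 -1
2 3 40 0 0 1.5 1
3 3 80 20 0 1.2 2
4 3 80 -20 0 1.2 2
5 3 120 40 0 1.0 3
6 2 -50 0 0 1.0 1
7 2 -120 0 0 1.0 6
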