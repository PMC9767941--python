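# background-correlation benchmark with causal contamination
M: 100000
K: 2
Psi: 0.5
Pi: 0.5
p_effect: 0.1
e_chi2: [1.3, 1.3]
replicates: 20
seed: 7
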