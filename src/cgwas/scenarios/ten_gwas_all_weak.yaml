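# all ten GWASs with a weak true effect E(chi2) = 1.1
M: 50000
Psi: 0.5
Pi: 0.5
p_effect: 0.1
e_chi2: [1.1, 1.1, 1.1, 1.1, 1.1, 1.1, 1.1, 1.1, 1.1, 1.1]
replicates: 100
seed: 5
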