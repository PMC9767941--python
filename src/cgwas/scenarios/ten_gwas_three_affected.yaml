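# three GWASs with true effects E(chi2) in {1.6, 1.3, 1.1}, seven null
M: 50000
Psi: 0.5
Pi: 0.5
p_effect: 0.1
e_chi2: [1.6, 1.3, 1.1, 1, 1, 1, 1, 1, 1, 1]
replicates: 100
seed: 3
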