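# two GWASs with equal true effects, E(chi2) = 1.3; one cell of the
# psi x pi power grid (vary Psi/Pi via overrides)
M: 50000
K: 2
Psi: 0.2
Pi: 0.8
p_effect: 0.1
e_chi2: [1.3, 1.3]
replicates: 100
seed: 1
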