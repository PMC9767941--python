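# pure-null type-I-error study: ten correlated GWASs, no effects
M: 50000
Psi: 0.5
Pi: 0.0
p_effect: 0.0
replicates: 400
seed: 8
K: 10
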