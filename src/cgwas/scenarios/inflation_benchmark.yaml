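# inflation-estimation benchmark: I = 0.1 plus 20% causal variants
M: 100000
K: 1
Psi: 0.0
Pi: 0.0
p_effect: 0.2
theta: 1.4142135623730951
inflate: 0.1
replicates: 20
seed: 6
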