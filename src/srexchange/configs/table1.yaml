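# Default rate constants and pools of the Cand1 exchange cycle (nM, s).
experiment: consistency
params:
  Ksr: 2.25e-4
  Ksr_prime: 650.0
  Kca: 1.73e-5
  Kca_prime: 50.0
  ksr: 9.0e-7
  ksr_prime: 1.3
  kca: 1.0e-5
  kca_prime: 0.04
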