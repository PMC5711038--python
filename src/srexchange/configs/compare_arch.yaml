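# Natural (+Cand1, tight binding) vs. matched weak-binding (-Cand1) design.
experiment: compare_arch
options:
  mode: sequential
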