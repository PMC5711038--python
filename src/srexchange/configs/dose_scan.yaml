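# Substrate half-life vs. total Cand1 (30 nM cognate receptor, 300 nM
# substrate bolus, diffusion-limited binding).
experiment: dose_scan
totals:
  cul1_total: 300.0
  cand1_total: 100.0
  sr_totals: [30.0, 630.0]
  substrate_totals: [300.0]
substrate:
  kon: 1.0e+8
  koff: 1.0
  kdeg: 0.004
  receptor: 0
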