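# One-parameter calibration of kca' against an observed exchange rate.
experiment: calibrate
options:
  target_kobs: 0.07
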