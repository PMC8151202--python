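# Single oral dose of trimethoprim: baseline exposure simulation.
victim: trimethoprim
victim_regimen:
  dose_mg: 210
  times_min: [0.0]
t_window_h: 24
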