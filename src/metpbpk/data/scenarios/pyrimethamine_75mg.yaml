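# Single oral dose of pyrimethamine: baseline exposure simulation.
victim: pyrimethamine
victim_regimen:
  dose_mg: 75
  times_min: [0.0]
t_window_h: 48
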