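# DDI co-simulation: metformin 250 mg with cimetidine 400 mg.
victim: metformin
victim_regimen:
  dose_mg: 250
  times_min: [1440.0]
perpetrator: cimetidine
perp_regimen:
  dose_mg: 400
  times_min: [0.0, 720.0, 1440.0, 2160.0]
t_window_h: 24
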