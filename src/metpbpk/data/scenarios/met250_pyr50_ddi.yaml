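# DDI co-simulation: metformin 250 mg with pyrimethamine 50 mg.
victim: metformin
victim_regimen:
  dose_mg: 250
  times_min: [0.0]
perpetrator: pyrimethamine
perp_regimen:
  dose_mg: 50
  times_min: [0.0]
t_window_h: 24
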