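# DDI co-simulation: metformin 850 mg with ondansetron 8 mg.
victim: metformin
victim_regimen:
  dose_mg: 850
  times_min: [0.0]
perpetrator: ondansetron
perp_regimen:
  dose_mg: 8
  times_min: [0.0]
t_window_h: 24
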