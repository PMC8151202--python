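# DDI co-simulation: metformin 500 mg with rabeprazole 20 mg.
victim: metformin
victim_regimen:
  dose_mg: 500
  times_min: [0.0]
perpetrator: rabeprazole
perp_regimen:
  dose_mg: 20
  times_min: [0.0]
t_window_h: 24
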