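# Rabeprazole: perpetrator, well-stirred liver and kidney; enteric-coated
# dosage form introduces an absorption lag.
name: rabeprazole
molar_mass: 359.44
f_ub: 0.04
R_b: 0.75
ka_fixed: 0.029
lag_time: 60.0           # min, dosage-form lag
CLint_met: 955.6
CLint_renal: 0.0
Ki_OCT1: 3.0
Ki_OCT2: 5.7
Ki_OCT3: 3.0
Ki_MATE: 4.60
K_per:
  heart: 1.0
  brain: 1.0
  muscle: 1.0
  adipose: 1.0
  skin: 1.0
  rest: 1.0
liver_model: well_stirred
kidney_model: well_stirred
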