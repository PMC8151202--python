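# Verapamil: perpetrator, well-stirred liver and kidney.  No MATE
# inhibition constant is reported, so MATE inhibition is disabled.
name: verapamil
molar_mass: 454.6
f_ub: 0.14
R_b: 0.68
P_eff: 0.0156
CLint_met: 17883.0
CLint_renal: 0.0
Ki_OCT1: 9.62
Ki_OCT2: 3.24
Ki_OCT3: 3.6
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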