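# Ondansetron: perpetrator, well-stirred liver and kidney; negligible renal
# excretion (hepatically cleared).
name: ondansetron
molar_mass: 293.36
f_ub: 0.325
R_b: 0.83
P_eff: 0.012
CLint_met: 1365.14
CLint_renal: 0.0
Ki_OCT1: 0.27
Ki_OCT2: 0.89
Ki_OCT3: 17.4
Ki_MATE: 0.01
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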