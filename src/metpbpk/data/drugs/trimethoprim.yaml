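# Trimethoprim: perpetrator, well-stirred liver and kidney.
name: trimethoprim
molar_mass: 290.32
f_ub: 0.43
R_b: 1.29
ka_fixed: 0.0355
CLint_met: 52.4
CLint_renal: 194.8624886865268    # back-calculated from CL_renal 77.86 mL/min
Ki_OCT1: 27.7
Ki_OCT2: 19.8
Ki_OCT3: 12.3
Ki_MATE: 0.51
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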