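# Pyrimethamine: perpetrator, well-stirred liver and kidney.  The OCT3
# inhibition constant is a reported lower bound (">100 uM"); simulations
# use the bound value.
name: pyrimethamine
molar_mass: 248.71
f_ub: 0.15
R_b: 0.86
ka_fixed: 0.062          # 1/min
CLint_met: 27.29
CLint_renal: 3.1346726934841858   # back-calculated from CL_renal 0.47 mL/min
Ki_OCT1: 4.46
Ki_OCT2: 0.61
Ki_OCT3: 100.0
ki_oct3_is_lower_bound: true
Ki_MATE: 0.02
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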