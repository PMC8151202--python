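# Cimetidine: perpetrator with transporter-explicit liver and kidney.
# Renal uptake is OCT2 plus a parallel, non-inhibited OAT3 route; MATE1 and
# MATE2-K efflux clearances are summed (17.67 + 11.87 uL/min/1e6 cells).
name: cimetidine
molar_mass: 252.34
f_ub: 0.82
R_b: 0.97
P_eff: 0.012
CLint_up_OCT1: 200.0
CLint_pd: 100.0          # calibrated (see docs/methods.md)
CLint_met: 188.3
CLint_up_OCT2: 29.89     # uL/min/1e6 tubule cells
CLint_eff_MATE: 29.54
CLint_up_OAT3: 7.63
renal_units: per_cell
Ki_OCT1: 101.0
Ki_OCT2: 2.97
Ki_OCT3: 45.7
Ki_MATE: 0.65
K_gb: 1.0
K_hb: 1.0
K_rb: 16.0               # renal accumulation, calibrated (cimetidine
                         # concentrates strongly in kidney tissue)
K_lub: 1.0
K_spb: 1.0
K_per:                   # lean-tissue ratios calibrated jointly
  heart: 0.65
  brain: 0.3
  muscle: 0.65
  adipose: 0.3
  skin: 0.65
  rest: 0.65
liver_model: transporter_explicit
kidney_model: transporter_explicit
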