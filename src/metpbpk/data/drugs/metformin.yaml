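# Metformin: victim drug; transporter-explicit liver (OCT1) and kidney
# (OCT2 uptake / MATE efflux in series), saturable OCT3/PMAT intestinal
# uptake.  Renal transporter clearances are per million tubule cells and
# are scaled to whole-body mL/min at load time.
name: metformin
molar_mass: 129.16
f_ub: 1.0
R_b: 1.0
P_eff: 0.00311          # cm/min
Km_OCT3: 2.46           # mM
Vmax_OCT3: 12.08        # nmol/mg protein/min
Km_PMAT: 1.68
Vmax_PMAT: 15.28
# in-vivo scaling of the S9-derived Vmax (calibrated once against the
# baseline oral profile; see docs/methods.md)
sf_OCT3: 0.05412
sf_PMAT: 0.02605
CLint_up_OCT1: 63.95    # mL/min
CLint_pd: 1.0           # mL/min, passive hepatocyte exchange (calibrated)
CLint_met: 110.57       # mL/min
CLint_up_OCT2: 14.2     # uL/min/1e6 tubule cells
CLint_eff_MATE: 16.6
renal_units: per_cell
K_gb: 1.623             # calibrated
K_hb: 1.0
K_rb: 1.0
K_lub: 1.0
K_spb: 1.0
K_per:                  # lean-tissue ratios calibrated jointly
  heart: 1.993
  brain: 0.1
  muscle: 1.993
  adipose: 0.15
  skin: 1.993
  rest: 1.993
liver_model: transporter_explicit
kidney_model: transporter_explicit
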