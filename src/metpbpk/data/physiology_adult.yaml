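# Reference adult (70 kg) physiology: blood flows (mL/min) and volumes (mL).
# Liver inflow = hepatic artery + spleen + gut wall (portal); kidney and
# peripheral tissues return directly to the venous pool.
body_weight: 70.0
Q_ha: 300.0
Q_sp: 150.0
Q_gw: [150.0, 450.0, 400.0]    # duodenum, jejunum, ileum enterocyte flow
Q_r: 1100.0
Q_per:
  heart: 240.0
  brain: 700.0
  muscle: 1050.0
  adipose: 260.0
  skin: 300.0
  rest: 500.0
V_art: 1000.0
V_ven: 3500.0
V_lu: 1200.0
V_sp: 180.0
V_hb: 608.3      # hepatic blood
V_hc: 1081.7     # hepatocytes
V_rb: 33.8       # renal blood
V_re: 246.2      # renal tubule cells
V_gw: [70.0, 350.0, 280.0]
V_per:
  heart: 330.0
  brain: 1450.0
  muscle: 29000.0
  adipose: 13000.0
  skin: 3300.0
  rest: 8000.0
GFR_per_70kg: 120.0
RAF: 3.0
tubule_density: 6.0e+7         # proximal tubule cells per g kidney
kidney_mass_per_kg: 4.3        # g kidney per kg body weight
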