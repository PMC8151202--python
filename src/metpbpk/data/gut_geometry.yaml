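# Gut transit-chain geometry and regional transporter scaling for the
# absorbing segments (duodenum, jejunum, ileum).  Caecum/colon form a
# terminal non-absorbing sink.
radius_cm: [2.0, 1.63, 1.45]
V_lumen: [314.2, 2170.19, 2609.05]       # mL
PBSF: [2790.65, 14465.81, 11219.5]       # mg S9 protein per segment
tsf_ex_oct3: [1.19, 1.0, 1.155]          # regional OCT3 expression (jejunum = 1)
pH: [5.5, 6.5, 7.5]
tsf_ph_oct3: {5.5: 0.35, 6.5: 0.74, 7.5: 1.0}
tsf_ph_pmat: {5.5: 1.0, 6.5: 0.48, 7.5: 0.11}
# transit rate constants, 1/min (calibrated once against the baseline oral
# profile, see docs/methods.md): gastric emptying t1/2 ~ 60 min; segmental
# small-intestinal residence ~ 23/147/136 min (~5 h total, split by length)
K_t0: 0.011557074120369349
K_t: [0.04303208243190418, 0.006794539331879607, 0.007335112814207337]
passive_fraction: 0.30
f_oct3: 0.50
f_pmat: 0.20
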