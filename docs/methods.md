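# Methods

## Model structure and assumptions

The model is a whole-body system of mass-balance ODEs over compartment
*amounts* (nmol).  Internal units are fixed throughout: volumes in mL, time
in min, flows in mL/min, concentrations in µM (nmol/mL).  Transporter
kinetics are stored as reported — Km in mM (converted to µM at the flux),
Vmax in nmol/mg S9 protein/min, inhibition constants Ki in µM — and mass
units (µg/mL, µg·h/mL) appear only at the reporting boundary through the
compound molar mass.  Plasma concentration is venous blood concentration
divided by the blood/plasma ratio R_b.

Key structural assumptions:

* Absorption and transporter-mediated uptake occur only in duodenum,
  jejunum and ileum; material leaving the ileum is unabsorbed (caecum and
  colon are a terminal sink).  The stomach does not absorb.
* The apical pathway split for metformin is 50% OCT3, 20% PMAT, 30%
  passive ("other transporters"), encoded as the explicit 30% factor on
  the passive first-order term and enforced on the saturable routes during
  calibration (see below).  The split is assumed dose-independent.
* Victim liver and kidney are permeability-limited two-compartment organs
  (blood + cells); perpetrators without uptake kinetics use well-stirred
  single compartments.  Biliary secretion is neglected (negligible for
  metformin) and there is no enterohepatic recycling and no renal
  reabsorption.
* All peripheral tissues are flow-limited with constant tissue-to-blood
  ratios; only linear body-weight scaling is applied to the renal tubule
  cell count (60×10⁶ cells/g kidney × 4.3 g/kg), and GFR scales linearly
  from 120 mL/min per 70 kg.
* The RAF (relative activity factor, 3.0) scales the blood→cell OCT2/OAT3
  uptake and the cell→urine MATE efflux, but not the basolateral OCT2
  backflux.

## Inhibition model

Every inhibitable flux is divided by `1 + I/Ki` with the inhibitor
concentration taken at the substrate-binding face of the transporter:
segment lumen concentration for intestinal OCT3, unbound sinusoidal blood
for hepatic OCT1, unbound renal blood for the OCT2 uptake step, and unbound
tubule-cell concentration for MATE efflux.  A missing Ki means the
compound does not inhibit that transporter.

**The basolateral OCT2 backflux is not inhibited.**  Reported Ki values
describe competition at the extracellular substrate face; no
cytoplasmic-face affinity is available for any of the perpetrators.  The
choice also matters quantitatively: if the backflux were inhibited by the
intracellular perpetrator with the same Ki as the uptake step, tubule-side
inhibition would throttle both exit routes in a fixed ratio and the serial
secretion clearance could never fall below ≈43% of the uptake-limited
value, capping the predicted cimetidine interaction near AUCR 1.26 — far
below the interaction the complete model is known to produce.  With the
backflux free, MATE inhibition lets drug return to blood and secretion
collapses toward the glomerular floor, reproducing the observed DDI range.

**Sensitivity-scan convention.**  Ki scans use an *inhibition-potency
multiplier*: multiplier m rescales the constant to Ki/m, so m = 10 is
ten-fold stronger inhibition and m → 0 removes the pathway.  Under this
convention the scan outputs are monotone in the physically required
direction (victim AUC non-decreasing in Ki_MATE of the perpetrator,
non-increasing in Ki_OCT3).

## Parameters

Compound constants (unbound fraction, blood/plasma ratio, permeability or
fixed ka, transporter clearances and Km/Vmax pairs, Ki sets, molar masses)
are packaged as one YAML fixture per drug and validated on load; per-cell
renal clearances (µL/min/10⁶ tubule cells) are scaled to whole-body mL/min
(e.g. 14.2 → 256.45 and 16.6 → 299.80 mL/min at 70 kg).  Well-stirred
intrinsic clearances are back-calculated from observed organ clearances by
exact inversion of CL = f_ub·CL_int·Q/(f_ub·CL_int + Q); the inversion
refuses extraction ratios ≥ 1.  A Ki reported only as a lower bound
(pyrimethamine OCT3, "> 100 µM") is stored as the bound with a flag and
used at the bound — a conservative choice.  Metformin's hepatic
CL_int,met = 110.57 mL/min is used as tabulated even though metformin is
conventionally considered unmetabolized; it represents the compound's
minor hepatic elimination and is flagged here rather than silently
dropped.  Rabeprazole's MATE Ki (4.60 µM) is likewise used as tabulated.

The adult-70-kg physiology (flows, volumes) uses standard reference
values; liver (608.3 mL blood / 1081.7 mL hepatocytes) and kidney
(33.8 mL blood / 246.2 mL tubule) sub-volumes, GFR, RAF and tubule-count
scaling are fixed constants of the model.  Hepatic inflow is hepatic
artery (300) + spleen (150) + gut wall (1000) = 1450 mL/min; renal flow is
1100 mL/min; cardiac output 5600 mL/min.

## Calibration of non-identifiable parameters

A handful of quantities cannot be taken from in-vitro tables: tissue
partition ratios, the hepatocyte passive exchange clearance CL_int,pd, the
in-vivo scaling of the S9-derived intestinal Vmax values, and the
gastrointestinal transit constants.  These were fitted **once**, jointly,
against the baseline oral metformin behaviour (250 and 750 mg exposure,
the transit-rate and renal-knockout sensitivities, and the intestinal
pathway split), and then frozen into the packaged fixtures; no further
adjustment is made anywhere in the code or tests.  Final values:

| quantity | value | note |
|---|---|---|
| metformin sf_OCT3 / sf_PMAT | 0.05412 / 0.02605 | in-vivo scaling of S9 Vmax; keeps OCT3 ≈ 50% and PMAT ≈ 20% of absorption with strong saturation at mM lumen concentrations |
| metformin CL_int,pd | 1.0 mL/min | hepatic uptake is OCT1-limited |
| metformin K (lean tissues) | 1.993 | V_ss ≈ 110 L; brain 0.1, adipose 0.15 |
| metformin K_g:b | 1.623 | enterocyte partition |
| gastric emptying K_t0 | 0.01156 /min | t½ ≈ 60 min |
| intestinal K_t,i | 0.0430 / 0.00679 / 0.00734 /min | segmental residence ≈ 23/147/136 min (≈ 5 h) |
| cimetidine CL_int,pd | 100 mL/min | |
| cimetidine K_r:b | 16 | renal tissue accumulation driving intracellular MATE inhibition |
| cimetidine K (lean tissues) | 0.65 | |

Headline outputs are insensitive to metformin CL_int,pd across its
plausible range because uptake (63.95 mL/min) limits hepatic clearance;
the OCT1-knockout contribution (+18.5% AUC) brackets the hepatic share.
The DDI scenario doses cimetidine 400 mg twice daily with the metformin
dose given at perpetrator steady state (24 h after the first cimetidine
dose), matching the clinical design of the interaction studies; the other
perpetrators are co-administered at t = 0.

## Gut flux driving concentration

The saturable OCT3/PMAT uptake is driven by the **lumen** concentration
A_i/V_lumen,i by default.  An alternative reading drives it by the
enterocyte concentration A_gw,i/V_gw,i/K_g:b, which is zero at t = 0 and
physiologically odd for apical uptake; it is retained as
`SolverOptions(gut_flux_driving="enterocyte")` for comparison.  Only the
lumen form produces saturation on the mM scale of the reported Km values
and hence the observed dose-dependent oral clearance.

## Population simulation and synthetic data

Inter-individual variability is an exponential (lognormal) model on five
parameters — Vmax_OCT3 (via its scaling factor), CL_int,up,OCT1,
CL_int,up,OCT2, CL_int,eff,MATE and the transit constants (one shared
multiplier) — with a multiplicative lognormal residual error on observed
concentrations.  Random-effect magnitudes are not identifiable from the
packaged data, so defaults of 30% CV per parameter and 20% residual CV are
used and exposed in `PopulationSpec`; a CV is converted to the log-scale
SD by ω = √log(1+CV²) so the median subject is the typical subject.  VPC
bands are the 5/50/95 percentiles across subjects, summarized per time
point by the median and 90% interval **across replicates**.

The synthetic-data generator emulates sparse clinical sampling
(0.5–24 h grid), residual assay/biological noise, and population spread.
It does not emulate between-study heterogeneity (different formulations,
food effects, analytical platforms), nonzero baseline concentrations, or
dropout — so passing recovery and coverage tests demonstrates internal
consistency of the estimation machinery, not robustness to real-data
artifacts.  Generated datasets embed the generating truth and seed, and
round-trip losslessly through CSV (`%.17g` write, round-trip parse).

Parameter recovery minimizes squared log-concentration residuals with a
bounded trust-region least-squares in log-parameter space.  The serial
OCT2/MATE pair is structurally non-identifiable from plasma data alone
(rebalancing the pair at constant serial secretion clearance leaves the
objective nearly flat); the test suite asserts this flatness rather than
pretending the pair is estimable.

## Numerics

* Integrator: LSODA with rtol 1e-8, atol 1e-10 nmol (production defaults;
  exposed in `SolverOptions`).  Oral doses are state jumps added to the
  stomach at the dose time plus any dosage-form lag, with the integration
  restarted at each event.
* Reporting grid: 2-min spacing by default; Cmax is the grid maximum
  (refinement changes it by < 0.5%), AUC is trapezoidal on the grid over
  the analysis window (24 h for metformin scenarios, 48 h for long
  half-life perpetrators).
* Concentrations are floored at zero inside flux evaluation only; the
  state itself is never clipped, so mass balance is exact by construction
  (every flux leaves one compartment and enters another or a cumulative
  urine/metabolite/fecal sink).  Simulated mass-balance error stays below
  1e-6 of the dose at all output times.
* Degenerate inputs: zero dose gives identically zero trajectories; zero
  population variance collapses VPC bands onto the deterministic profile;
  a missing Ki yields a unit inhibition divisor.

## Known limitations

* Partition ratios are config inputs, not predicted from tissue
  composition; perpetrators other than cimetidine default to unity lean
  tissue ratios, so their distribution phases are approximate (their role
  here is exposure-driving, not tissue prediction).
* Cimetidine's own predicted exposure runs ~15–20% below the reference
  predictions because its renal secretion model, taken at face value,
  clears faster than the reported profile; the DDI predictions are driven
  by its unbound exposure at the inhibition sites, which the calibration
  anchors instead.
* The intestinal pH effect acts only through the discrete 5.5/6.5/7.5
  activity lookup; no continuous pH-activity relation is invented.
* Single-dose immediate-release scenarios only (one lag time for enteric
  coating); no IV dosing, no dissolution model, no disease- or
  genotype-shifted physiology.
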