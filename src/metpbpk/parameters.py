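"""Model constants, parameter containers and closed-form parameter derivations.

Internal unit system
--------------------
amounts       nmol
volumes       mL
time          min
flows         mL/min
concentration uM (= nmol/mL)
Km            stored in mM as reported, converted to uM where consumed
Vmax          nmol / mg S9 protein / min
Ki            uM

Conversion to mass units (ug/mL, ug.h/mL) happens only at the reporting
boundary, via the compound molar mass.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml

#: peripheral, flow-limited tissues lumped outside the mechanistic organs
PERIPHERAL_TISSUES = ("heart", "brain", "muscle", "adipose", "skin", "rest")

#: gut segments where absorption (passive + OCT3/PMAT) takes place
ABSORBING_SEGMENTS = ("duodenum", "jejunum", "ileum")

WELL_STIRRED = "well_stirred"
TRANSPORTER_EXPLICIT = "transporter_explicit"


class ParameterError(ValueError):
    """A drug/physiology parameter violates its physical domain."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhysiologyTable:
    """Reference adult physiology: organ volumes, blood flows, renal scalars.

    Flows are blood flows in mL/min, volumes in mL, for a default 70 kg
    adult.  The liver receives the hepatic artery plus the portal outflow of
    spleen and gut wall; the venous pool collects liver, kidney and the
    peripheral tissues and feeds the lung, which returns to the arterial
    pool.
    """

    body_weight: float = 70.0
    # flows, mL/min
    Q_ha: float = 300.0            # hepatic artery
    Q_sp: float = 150.0            # spleen (portal tributary)
    Q_gw: tuple = (150.0, 450.0, 400.0)   # gut-wall flow per absorbing segment
    Q_r: float = 1100.0            # kidney
    Q_per: dict = field(default_factory=lambda: {
        "heart": 240.0, "brain": 700.0, "muscle": 1050.0,
        "adipose": 260.0, "skin": 300.0, "rest": 500.0,
    })
    # volumes, mL
    V_art: float = 1000.0
    V_ven: float = 3500.0
    V_lu: float = 1200.0
    V_sp: float = 180.0
    V_hb: float = 608.3            # hepatic blood
    V_hc: float = 1081.7           # hepatocytes
    V_rb: float = 33.8             # renal blood
    V_re: float = 246.2            # renal tubule cells
    V_gw: tuple = (70.0, 350.0, 280.0)    # enterocyte volume per segment
    V_per: dict = field(default_factory=lambda: {
        "heart": 330.0, "brain": 1450.0, "muscle": 29000.0,
        "adipose": 13000.0, "skin": 3300.0, "rest": 8000.0,
    })
    # renal scalars
    GFR_per_70kg: float = 120.0            # mL/min per 70 kg
    RAF: float = 3.0                       # in-vitro -> in-vivo activity factor
    tubule_density: float = 60e6           # proximal tubule cells per g kidney
    kidney_mass_per_kg: float = 4.3        # g kidney per kg body weight

    # ----- derived -----
    @property
    def Q_L(self) -> float:
        """Total liver outflow: hepatic artery + spleen + gut wall."""
        return self.Q_ha + self.Q_sp + sum(self.Q_gw)

    @property
    def Q_total(self) -> float:
        """Cardiac output: all flows returning to the venous pool."""
        return self.Q_L + self.Q_r + sum(self.Q_per.values())

    @property
    def V_h(self) -> float:
        return self.V_hb + self.V_hc

    @property
    def V_r(self) -> float:
        return self.V_rb + self.V_re

    @property
    def GFR(self) -> float:
        """Glomerular filtration rate scaled linearly with body weight."""
        return self.GFR_per_70kg * self.body_weight / 70.0

    def validate(self) -> "PhysiologyTable":
        for name in ("Q_ha", "Q_sp", "Q_r", "V_art", "V_ven", "V_lu", "V_sp",
                     "V_hb", "V_hc", "V_rb", "V_re", "body_weight"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"physiology field {name} must be > 0")
        if any(q <= 0 for q in self.Q_gw) or any(v <= 0 for v in self.V_gw):
            raise ParameterError("gut-wall flows/volumes must be > 0")
        if set(self.Q_per) != set(PERIPHERAL_TISSUES) or set(self.V_per) != set(PERIPHERAL_TISSUES):
            raise ParameterError(f"peripheral tissues must be exactly {PERIPHERAL_TISSUES}")
        return self


@dataclass(frozen=True)
class GutGeometry:
    """Gut transit chain geometry, protein scaling and regional activity.

    The lumen is a stomach -> duodenum -> jejunum -> ileum transit chain;
    material leaving the ileum enters a terminal, non-absorbing caecum/colon
    sink counted as unabsorbed (fecal) drug.
    """

    radius_cm: tuple = (2.0, 1.63, 1.45)
    V_lumen: tuple = (314.2, 2170.19, 2609.05)          # mL
    PBSF: tuple = (2790.65, 14465.81, 11219.5)          # mg S9 protein
    tsf_ex_oct3: tuple = (1.19, 1.0, 1.155)             # regional OCT3 expression
    pH: tuple = (5.5, 6.5, 7.5)
    # discrete pH -> relative activity lookup (no interpolation is invented)
    tsf_ph_oct3: dict = field(default_factory=lambda: {5.5: 0.35, 6.5: 0.74, 7.5: 1.0})
    tsf_ph_pmat: dict = field(default_factory=lambda: {5.5: 1.0, 6.5: 0.48, 7.5: 0.11})
    # transit rate constants, 1/min (gastric emptying t1/2 ~ 60 min; small
    # intestinal transit ~ 5 h split across segments by length; calibrated
    # once against the baseline oral profile, see docs/methods.md)
    K_t0: float = 0.011557074120369349
    K_t: tuple = (0.04303208243190418, 0.006794539331879607, 0.007335112814207337)
    # assumed apical pathway split for the victim drug
    passive_fraction: float = 0.30
    f_oct3: float = 0.50
    f_pmat: float = 0.20

    def tsf_ph(self, transporter: str) -> tuple:
        table = self.tsf_ph_oct3 if transporter == "OCT3" else self.tsf_ph_pmat
        try:
            return tuple(table[p] for p in self.pH)
        except KeyError as exc:  # pragma: no cover - defensive
            raise ParameterError(f"no activity scalar tabulated for pH {exc}") from exc

    def with_ph(self, pH: tuple) -> "GutGeometry":
        return dataclasses.replace(self, pH=tuple(pH))

    def scale_transit(self, multiplier: float) -> "GutGeometry":
        """Multiply every gastrointestinal transit rate constant."""
        if multiplier <= 0:
            raise ParameterError("transit multiplier must be > 0")
        return dataclasses.replace(
            self, K_t0=self.K_t0 * multiplier,
            K_t=tuple(k * multiplier for k in self.K_t))

    def validate(self) -> "GutGeometry":
        n = len(ABSORBING_SEGMENTS)
        for name in ("radius_cm", "V_lumen", "PBSF", "tsf_ex_oct3", "pH", "K_t"):
            if len(getattr(self, name)) != n:
                raise ParameterError(f"{name} needs one entry per absorbing segment")
        if self.K_t0 <= 0 or any(k <= 0 for k in self.K_t):
            raise ParameterError("transit constants must be > 0")
        total = self.passive_fraction + self.f_oct3 + self.f_pmat
        if abs(total - 1.0) > 1e-9:
            raise ParameterError("apical pathway fractions must sum to 1")
        return self


@dataclass(frozen=True)
class DrugProfile:
    """Compound-specific constants: binding, permeability, transporter kinetics.

    Renal transporter clearances may be given per million tubule cells
    (``renal_units='per_cell'``, uL/min/1e6 cells) and are scaled to
    whole-body mL/min during validation, or directly as whole-body mL/min.
    A missing Ki means the compound does not inhibit that transporter.
    """

    name: str
    molar_mass: float                      # g/mol
    f_ub: float                            # unbound fraction in blood
    R_b: float                             # blood/plasma concentration ratio
    P_eff: Optional[float] = None          # cm/min
    ka_fixed: Optional[float] = None       # 1/min, overrides P_eff route
    lag_time: float = 0.0                  # min, dosage-form lag
    # intestinal Michaelis-Menten uptake (victim only)
    Km_OCT3: Optional[float] = None        # mM
    Vmax_OCT3: Optional[float] = None      # nmol/mg protein/min
    Km_PMAT: Optional[float] = None
    Vmax_PMAT: Optional[float] = None
    sf_OCT3: float = 1.0                   # in-vivo scaling of Vmax_OCT3
    sf_PMAT: float = 1.0
    # liver
    CLint_up_OCT1: float = 0.0             # mL/min
    CLint_pd: float = 0.0                  # mL/min, passive hepatocyte exchange
    CLint_met: float = 0.0                 # mL/min, hepatocyte metabolic clearance
    # kidney
    CLint_up_OCT2: float = 0.0
    CLint_eff_MATE: float = 0.0
    CLint_up_OAT3: float = 0.0
    renal_units: str = "whole_body"        # or "per_cell"
    CLint_renal: float = 0.0               # mL/min, well-stirred kidney
    # inhibition constants (uM); None => no inhibition of that transporter
    Ki_OCT1: Optional[float] = None
    Ki_OCT2: Optional[float] = None
    Ki_OCT3: Optional[float] = None
    Ki_MATE: Optional[float] = None
    ki_oct3_is_lower_bound: bool = False
    # tissue-to-blood concentration ratios
    K_gb: float = 1.0
    K_hb: float = 1.0
    K_rb: float = 1.0
    K_lub: float = 1.0
    K_spb: float = 1.0
    K_per: dict = field(default_factory=lambda: {t: 1.0 for t in PERIPHERAL_TISSUES})
    # organ sub-model selection
    liver_model: str = WELL_STIRRED
    kidney_model: str = WELL_STIRRED

    def ka(self, radius_cm: float) -> float:
        """Segmental first-order absorption rate constant (1/min)."""
        if self.ka_fixed is not None:
            return self.ka_fixed
        if self.P_eff is None:
            raise ParameterError(f"{self.name}: neither P_eff nor ka_fixed provided")
        return ka_from_peff(self.P_eff, radius_cm)

    @property
    def has_mm_uptake(self) -> bool:
        return self.Vmax_OCT3 is not None or self.Vmax_PMAT is not None

    def nmol_from_mg(self, dose_mg: float) -> float:
        return dose_mg / self.molar_mass * 1e6

    def ug_per_ml(self, conc_uM: float):
        """uM -> ug/mL for this compound."""
        return conc_uM * self.molar_mass / 1000.0


@dataclass(frozen=True)
class DoseRegimen:
    """Oral dosing schedule: dose per administration and administration times."""

    drug: str
    dose_mg: float
    times_min: tuple = (0.0,)
    lag_min: float = 0.0

    def validate(self) -> "DoseRegimen":
        if self.dose_mg < 0:
            raise ParameterError("dose_mg must be >= 0")
        times = tuple(self.times_min)
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ParameterError("administration times must be strictly increasing")
        if self.lag_min < 0:
            raise ParameterError("lag must be >= 0")
        return self


# ---------------------------------------------------------------------------
# closed-form parameter derivations
# ---------------------------------------------------------------------------


def ka_from_peff(P_eff: float, radius_cm: float) -> float:
    """Absorption rate constant from effective permeability: ka = 2*Peff/r.

    P_eff in cm/min, radius in cm, result in 1/min.
    """
    if P_eff <= 0 or radius_cm <= 0:
        raise ParameterError("P_eff and radius must be > 0")
    return 2.0 * P_eff / radius_cm


def scale_tubule_clearance(cl_per_1e6: float, body_weight: float = 70.0,
                           tubule_density: float = 60e6,
                           kidney_mass_per_kg: float = 4.3) -> float:
    """Scale a per-cell clearance (uL/min/1e6 cells) to whole body (mL/min).

    Total tubule cell count = density (cells/g kidney) x kidney mass
    (g/kg body weight) x body weight.
    """
    if cl_per_1e6 < 0:
        raise ParameterError("clearance must be >= 0")
    if body_weight <= 0 or tubule_density <= 0 or kidney_mass_per_kg <= 0:
        raise ParameterError("scaling constants must be > 0")
    n_million_cells = tubule_density * kidney_mass_per_kg * body_weight / 1e6
    return cl_per_1e6 * n_million_cells / 1000.0  # uL -> mL


def well_stirred_clearance(f_ub: float, CLint: float, Q: float) -> float:
    """Flow-limited organ clearance: CL = f_ub*CLint*Q / (f_ub*CLint + Q)."""
    if Q <= 0:
        raise ParameterError("organ blood flow must be > 0")
    denom = f_ub * CLint + Q
    return f_ub * CLint * Q / denom if denom > 0 else 0.0


def _invert_well_stirred(CL_organ: float, f_ub: float, Q: float, what: str) -> float:
    if CL_organ < 0:
        raise ParameterError(f"{what}: organ clearance must be >= 0")
    if CL_organ == 0.0:
        return 0.0
    if CL_organ >= Q:
        raise ParameterError(
            f"{what}: organ clearance {CL_organ} implies extraction ratio >= 1 "
            f"(organ flow {Q}); infeasible")
    if f_ub <= 0:
        raise ParameterError(f"{what}: f_ub must be > 0 when organ clearance > 0")
    return Q * CL_organ / (f_ub * (Q - CL_organ))


def back_calc_clint_met(CL_system: float, CL_renal: float, f_ub: float,
                        Q_L: float) -> float:
    """Hepatic intrinsic metabolic clearance from systemic and renal clearance.

    CL_liver = CL_system - CL_renal, then the well-stirred relation
    CL_liver = f_ub*CLint*Q_L/(f_ub*CLint + Q_L) is inverted for CLint.
    """
    if not 0 <= CL_renal <= CL_system:
        raise ParameterError("require 0 <= CL_renal <= CL_system")
    return _invert_well_stirred(CL_system - CL_renal, f_ub, Q_L, "CLint_met")


def back_calc_clint_renal(CL_renal: float, f_ub: float, Q_r: float) -> float:
    """Renal intrinsic clearance from observed renal clearance (well-stirred)."""
    return _invert_well_stirred(CL_renal, f_ub, Q_r, "CLint_renal")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_profile(profile: DrugProfile, phys: PhysiologyTable) -> DrugProfile:
    """Assert all profile invariants; scale per-cell renal clearances.

    Returns a checked profile in whole-body units.  Every violated invariant
    is reported with its field name.
    """
    errors = []
    p = profile
    if not 0 < p.f_ub <= 1:
        errors.append(f"f_ub={p.f_ub} outside (0, 1]")
    if p.R_b <= 0:
        errors.append(f"R_b={p.R_b} must be > 0")
    if p.molar_mass <= 0:
        errors.append(f"molar_mass={p.molar_mass} must be > 0")
    if p.P_eff is None and p.ka_fixed is None:
        errors.append("one of P_eff / ka_fixed is required for an absorbing drug")
    if p.P_eff is not None and p.ka_fixed is not None:
        errors.append("P_eff and ka_fixed are mutually exclusive")
    for name in ("CLint_up_OCT1", "CLint_pd", "CLint_met", "CLint_up_OCT2",
                 "CLint_eff_MATE", "CLint_up_OAT3", "CLint_renal",
                 "sf_OCT3", "sf_PMAT"):
        if getattr(p, name) < 0:
            errors.append(f"{name} must be >= 0")
    for name in ("Km_OCT3", "Km_PMAT"):
        v = getattr(p, name)
        if v is not None and v <= 0:
            errors.append(f"{name} must be > 0")
    for name in ("Vmax_OCT3", "Vmax_PMAT"):
        v = getattr(p, name)
        if v is not None and v < 0:
            errors.append(f"{name} must be >= 0")
    for name in ("Ki_OCT1", "Ki_OCT2", "Ki_OCT3", "Ki_MATE"):
        v = getattr(p, name)
        if v is not None and v <= 0:
            errors.append(f"{name} must be > 0 when present")
    for name in ("K_gb", "K_hb", "K_rb", "K_lub", "K_spb"):
        if getattr(p, name) <= 0:
            errors.append(f"{name} must be > 0")
    if set(p.K_per) != set(PERIPHERAL_TISSUES):
        errors.append(f"K_per must cover exactly {PERIPHERAL_TISSUES}")
    elif any(v <= 0 for v in p.K_per.values()):
        errors.append("all peripheral partition ratios must be > 0")
    if p.liver_model not in (WELL_STIRRED, TRANSPORTER_EXPLICIT):
        errors.append(f"unknown liver_model {p.liver_model!r}")
    if p.kidney_model not in (WELL_STIRRED, TRANSPORTER_EXPLICIT):
        errors.append(f"unknown kidney_model {p.kidney_model!r}")
    if p.liver_model == TRANSPORTER_EXPLICIT and p.CLint_up_OCT1 <= 0 and p.CLint_pd <= 0:
        errors.append("transporter-explicit liver requires CLint_up_OCT1 or CLint_pd")
    if p.kidney_model == TRANSPORTER_EXPLICIT and p.CLint_up_OCT2 <= 0 and p.CLint_up_OAT3 <= 0:
        errors.append("transporter-explicit kidney requires an uptake clearance")
    if p.renal_units not in ("whole_body", "per_cell"):
        errors.append(f"unknown renal_units {p.renal_units!r}")
    if p.Km_OCT3 is not None and p.Vmax_OCT3 is None:
        errors.append("Km_OCT3 given without Vmax_OCT3")
    if p.Km_PMAT is not None and p.Vmax_PMAT is None:
        errors.append("Km_PMAT given without Vmax_PMAT")
    if errors:
        raise ParameterError(f"invalid profile {p.name!r}: " + "; ".join(errors))

    if p.renal_units == "per_cell":
        kwargs = dict(body_weight=phys.body_weight,
                      tubule_density=phys.tubule_density,
                      kidney_mass_per_kg=phys.kidney_mass_per_kg)
        p = dataclasses.replace(
            p,
            CLint_up_OCT2=scale_tubule_clearance(p.CLint_up_OCT2, **kwargs),
            CLint_eff_MATE=scale_tubule_clearance(p.CLint_eff_MATE, **kwargs),
            CLint_up_OAT3=scale_tubule_clearance(p.CLint_up_OAT3, **kwargs),
            renal_units="whole_body",
        )
    return p


# ---------------------------------------------------------------------------
# packaged fixtures / config I/O
# ---------------------------------------------------------------------------

_TUPLE_FIELDS_GEOM = ("radius_cm", "V_lumen", "PBSF", "tsf_ex_oct3", "pH", "K_t")


def _data_root():
    return resources.files("metpbpk") / "data"


def profile_from_dict(d: dict) -> DrugProfile:
    d = dict(d)
    if "K_per" in d:
        d["K_per"] = {k: float(v) for k, v in d["K_per"].items()}
    return DrugProfile(**d)


def profile_to_dict(p: DrugProfile) -> dict:
    return dataclasses.asdict(p)


def load_drug(name_or_path, phys: Optional[PhysiologyTable] = None,
              validate: bool = True) -> DrugProfile:
    """Load a drug profile from a packaged fixture name or a YAML path."""
    path = _data_root() / "drugs" / f"{name_or_path}.yaml"
    try:
        text = path.read_text()
    except (FileNotFoundError, OSError):
        with open(name_or_path) as fh:
            text = fh.read()
    profile = profile_from_dict(yaml.safe_load(text))
    if validate:
        profile = validate_profile(profile, phys or default_physiology())
    return profile


def load_physiology(path=None) -> PhysiologyTable:
    if path is None:
        text = (_data_root() / "physiology_adult.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    d = yaml.safe_load(text)
    d["Q_gw"] = tuple(d["Q_gw"])
    d["V_gw"] = tuple(d["V_gw"])
    return PhysiologyTable(**d).validate()


def load_geometry(path=None) -> GutGeometry:
    if path is None:
        text = (_data_root() / "gut_geometry.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    d = yaml.safe_load(text)
    for k in _TUPLE_FIELDS_GEOM:
        if k in d:
            d[k] = tuple(d[k])
    for k in ("tsf_ph_oct3", "tsf_ph_pmat"):
        if k in d:
            d[k] = {float(p): float(v) for p, v in d[k].items()}
    return GutGeometry(**d).validate()


def default_physiology() -> PhysiologyTable:
    return load_physiology()


def default_geometry() -> GutGeometry:
    return load_geometry()


def packaged_drug_names() -> list:
    return sorted(p.name[:-5] for p in (_data_root() / "drugs").iterdir()
                  if p.name.endswith(".yaml"))


def export_parameters_csv(profiles, path) -> None:
    """Write validated parameter sets to CSV (one row per drug)."""
    import pandas as pd

    rows = []
    for p in profiles:
        d = profile_to_dict(p)
        kper = d.pop("K_per")
        d.update({f"K_{t}": v for t, v in kper.items()})
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)
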