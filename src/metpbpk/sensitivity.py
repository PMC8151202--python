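"""Parameter scans, pH scenarios and transporter knockout contributions.

Ki scans use an inhibition-potency multiplier: a multiplier m rescales the
perpetrator's inhibition constant to Ki/m, so m > 1 strengthens inhibition
and m -> 0 removes it.  Scan tables always include the baseline
(multiplier 1) row so ratios stay internally consistent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .parameters import (DoseRegimen, DrugProfile, GutGeometry,
                         ParameterError, PhysiologyTable)
from .simulator import SolverOptions, pk_metrics, simulate

KI_PARAMETERS = ("Ki_OCT1", "Ki_OCT2", "Ki_OCT3", "Ki_MATE")

#: regional pH sets for the three intestinal pH conditions
PH_CONDITIONS = {1: (5.5, 6.5, 7.5), 2: (6.5, 7.5, 7.5), 3: (7.5, 7.5, 7.5)}

#: knockout id -> DrugProfile field(s) set to zero on the victim
KNOCKOUTS = {
    "OCT1_liver": ("CLint_up_OCT1",),
    "OCT2_renal": ("CLint_up_OCT2",),
    "MATE_renal": ("CLint_eff_MATE",),
    "OCT3_gut": ("sf_OCT3",),
    "PMAT_gut": ("sf_PMAT",),
    "OCT2+MATE_renal": ("CLint_up_OCT2", "CLint_eff_MATE"),
}


@dataclass(frozen=True)
class ScanSpec:
    """A one-parameter sensitivity scan around a simulated scenario."""

    parameter: str                       # Ki_* | transit | ph_condition
    multipliers: tuple = (0.1, 1.0, 10.0)

    def validate(self) -> "ScanSpec":
        if self.parameter not in KI_PARAMETERS + ("transit", "ph_condition"):
            raise ParameterError(f"unknown scan parameter {self.parameter!r}")
        if self.parameter != "ph_condition":
            if any(mult <= 0 for mult in self.multipliers):
                raise ParameterError("multipliers must be > 0")
            if not any(abs(mult - 1.0) < 1e-12 for mult in self.multipliers):
                raise ParameterError("baseline multiplier 1 must be included")
        return self


@dataclass(frozen=True)
class ContributionReport:
    """AUC change when one transporter is removed from the model."""

    transporter: str
    auc_control: float
    auc_non_transporter: float

    @property
    def percent_contribution(self) -> float:
        return (self.auc_non_transporter - self.auc_control) / self.auc_control * 100.0


class _Scenario:
    """Victim (+ optional perpetrator) scenario bound to shared settings."""

    def __init__(self, victim, victim_regimen, perpetrator=None,
                 perp_regimen=None, phys=None, geom=None,
                 t_window_h=24.0, options=SolverOptions()):
        self.victim = victim
        self.victim_regimen = victim_regimen
        self.perpetrator = perpetrator
        self.perp_regimen = perp_regimen
        self.phys = phys
        self.geom = geom
        self.t_window_h = t_window_h
        self.options = options
        self.t_start = victim_regimen.times_min[0]
        self.t_end = self.t_start + t_window_h * 60.0

    def metrics(self, victim=None, perpetrator=None, geom=None,
                with_perpetrator=True):
        victim = victim or self.victim
        geom = geom if geom is not None else self.geom
        perp = perpetrator or self.perpetrator
        kwargs = {}
        if with_perpetrator and perp is not None:
            kwargs = {"perpetrator": perp, "perp_regimen": self.perp_regimen}
        res = simulate(victim, self.victim_regimen, self.phys, geom,
                       t_end_min=self.t_end, options=self.options, **kwargs)
        return pk_metrics(res, self.t_window_h, t_start_min=self.t_start)


def scan(spec: ScanSpec, victim: DrugProfile, victim_regimen: DoseRegimen,
         perpetrator: Optional[DrugProfile] = None,
         perp_regimen: Optional[DoseRegimen] = None,
         phys: Optional[PhysiologyTable] = None,
         geom: Optional[GutGeometry] = None, *, t_window_h: float = 24.0,
         options: SolverOptions = SolverOptions()) -> pd.DataFrame:
    """One co-simulation per multiplier; returns a tidy results table.

    For Ki scans the multiplier strengthens the perpetrator's inhibition of
    that transporter (Ki -> Ki/m).  For transit scans it multiplies every
    gastrointestinal transit constant.  AUCR/CmaxR columns are relative to
    the victim-alone simulation under baseline settings.
    """
    from .parameters import default_geometry

    spec.validate()
    geom = geom or default_geometry()
    sc = _Scenario(victim, victim_regimen, perpetrator, perp_regimen,
                   phys, geom, t_window_h, options)
    alone = sc.metrics(with_perpetrator=False)
    rows = []
    for mult in spec.multipliers:
        perp = perpetrator
        g = geom
        if spec.parameter in KI_PARAMETERS:
            if perpetrator is None:
                raise ParameterError("Ki scans require a perpetrator")
            ki = getattr(perpetrator, spec.parameter)
            if ki is not None:
                perp = dataclasses.replace(perpetrator,
                                           **{spec.parameter: ki / mult})
        elif spec.parameter == "transit":
            g = geom.scale_transit(mult)
        m = sc.metrics(perpetrator=perp, geom=g)
        rows.append({"parameter": spec.parameter, "multiplier": mult,
                     "cmax_ug_per_ml": m.cmax_ug_per_ml,
                     "auc_ug_h_per_ml": m.auc_ug_h_per_ml,
                     "aucr": m.auc_ug_h_per_ml / alone.auc_ug_h_per_ml,
                     "cmaxr": m.cmax_ug_per_ml / alone.cmax_ug_per_ml})
    return pd.DataFrame(rows)


def transit_scan(victim: DrugProfile, victim_regimen: DoseRegimen,
                 phys: Optional[PhysiologyTable] = None,
                 geom: Optional[GutGeometry] = None, *,
                 multipliers: Sequence[float] = (0.5, 1.0, 2.0),
                 t_window_h: float = 24.0,
                 options: SolverOptions = SolverOptions()) -> pd.DataFrame:
    """AUC/Cmax change when all gastrointestinal transit constants scale."""
    from .parameters import default_geometry

    geom = geom or default_geometry()
    sc = _Scenario(victim, victim_regimen, phys=phys, geom=geom,
                   t_window_h=t_window_h, options=options)
    base = sc.metrics()
    rows = []
    for mult in multipliers:
        if mult <= 0:
            raise ParameterError("transit multipliers must be > 0")
        m = base if mult == 1.0 else sc.metrics(geom=geom.scale_transit(mult))
        rows.append({"multiplier": float(mult),
                     "cmax_ug_per_ml": m.cmax_ug_per_ml,
                     "auc_ug_h_per_ml": m.auc_ug_h_per_ml,
                     "auc_change_pct": (m.auc_ug_h_per_ml - base.auc_ug_h_per_ml)
                     / base.auc_ug_h_per_ml * 100.0})
    return pd.DataFrame(rows)


def ph_scenario(condition: int, victim: DrugProfile,
                victim_regimen: DoseRegimen,
                phys: Optional[PhysiologyTable] = None,
                geom: Optional[GutGeometry] = None, *,
                t_window_h: float = 24.0,
                options: SolverOptions = SolverOptions()):
    """Exposure under one of the regional intestinal pH conditions.

    Condition 1 is the control (duodenum/jejunum/ileum at 5.5/6.5/7.5);
    conditions 2 and 3 shift segments toward pH 7.5, raising OCT3 activity
    and lowering PMAT activity through the discrete pH lookup tables.
    """
    from .parameters import default_geometry

    if condition not in PH_CONDITIONS:
        raise ParameterError(f"pH condition must be one of {sorted(PH_CONDITIONS)}")
    geom = (geom or default_geometry()).with_ph(PH_CONDITIONS[condition])
    sc = _Scenario(victim, victim_regimen, phys=phys, geom=geom,
                   t_window_h=t_window_h, options=options)
    return sc.metrics()


def knockout(profile: DrugProfile, transporter: str) -> DrugProfile:
    """Profile with the named transporter clearance/activity set to zero."""
    if transporter not in KNOCKOUTS:
        raise ParameterError(f"unknown transporter {transporter!r}; "
                             f"choose from {sorted(KNOCKOUTS)}")
    return dataclasses.replace(profile,
                               **{f: 0.0 for f in KNOCKOUTS[transporter]})


def knockout_contribution(transporter: str, victim: DrugProfile,
                          victim_regimen: DoseRegimen,
                          phys: Optional[PhysiologyTable] = None,
                          geom: Optional[GutGeometry] = None, *,
                          t_window_h: float = 24.0,
                          options: SolverOptions = SolverOptions()) -> ContributionReport:
    """Percent AUC contribution of a transporter by deletion from the model."""
    sc = _Scenario(victim, victim_regimen, phys=phys, geom=geom,
                   t_window_h=t_window_h, options=options)
    base = sc.metrics()
    ko = sc.metrics(victim=knockout(victim, transporter))
    return ContributionReport(transporter=transporter,
                              auc_control=base.auc_ug_h_per_ml,
                              auc_non_transporter=ko.auc_ug_h_per_ml)
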