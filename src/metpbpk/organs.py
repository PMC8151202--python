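"""Organ-level right-hand sides of the whole-body circulation model.

Every function here is a pure derivative builder: it reads a state vector of
compartment amounts (nmol) and accumulates contributions into a derivative
array.  Each flux is added to exactly one compartment and subtracted from
exactly one compartment (or a cumulative sink), so mass balance holds by
construction.  Concentrations are floored at zero when evaluating fluxes;
the state itself is never clipped.

Compartment layout is per drug and depends on whether the liver and kidney
are transporter-explicit (separate blood/cell compartments) or well-stirred
(single compartment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (ABSORBING_SEGMENTS, PERIPHERAL_TISSUES,
                         TRANSPORTER_EXPLICIT, WELL_STIRRED, DrugProfile,
                         GutGeometry, ParameterError, PhysiologyTable)

#: cumulative elimination / loss sinks
SINKS = ("urine_cum", "met_cum", "fecal_cum")


class StateLayout:
    """Named index map from compartment name to state-vector position."""

    def __init__(self, profile: DrugProfile):
        names = ["stomach"]
        names += [f"lumen_{s}" for s in ABSORBING_SEGMENTS]
        names += [f"gw_{s}" for s in ABSORBING_SEGMENTS]
        if profile.liver_model == TRANSPORTER_EXPLICIT:
            names += ["liver_blood", "liver_cell"]
        else:
            names += ["liver"]
        if profile.kidney_model == TRANSPORTER_EXPLICIT:
            names += ["kidney_blood", "tubule"]
        else:
            names += ["kidney"]
        names += ["art", "ven", "lung", "spleen"]
        names += list(PERIPHERAL_TISSUES)
        names += list(SINKS)
        self.names = tuple(names)
        self.index = {n: i for i, n in enumerate(names)}
        self.n = len(names)

    def __getitem__(self, name: str) -> int:
        return self.index[name]

    def zeros(self) -> np.ndarray:
        return np.zeros(self.n)


@dataclass(frozen=True)
class InhibitionContext:
    """Perpetrator exposure at each inhibitable transporter site (uM).

    ``lumen`` holds the perpetrator lumen concentration per absorbing
    segment (drives intestinal OCT3 inhibition); the blood/tubule entries
    are unbound concentrations at the liver sinusoid, renal basolateral
    membrane and tubule-cell interior.
    """

    lumen: tuple = (0.0, 0.0, 0.0)
    liver_blood_unbound: float = 0.0
    kidney_blood_unbound: float = 0.0
    tubule_unbound: float = 0.0
    # the inhibitor's Ki set (None entries mean no inhibition)
    Ki_OCT1: float | None = None
    Ki_OCT2: float | None = None
    Ki_OCT3: float | None = None
    Ki_MATE: float | None = None


NO_INHIBITION = InhibitionContext()


# ---------------------------------------------------------------------------
# flux primitives
# ---------------------------------------------------------------------------


def competitive_factor(inhibitor_conc: float, Ki: float | None) -> float:
    """Competitive-inhibition divisor 1 + I/Ki; absent Ki means no inhibition."""
    if Ki is None:
        return 1.0
    if Ki <= 0:
        raise ParameterError("Ki must be > 0")
    return 1.0 + max(inhibitor_conc, 0.0) / Ki


def lumen_screening_conc(dose_mg: float, molar_mass: float,
                         volume_mL: float = 250.0) -> float:
    """Screening-level lumen concentration (mM) as dose dissolved in 250 mL."""
    if dose_mg < 0 or molar_mass <= 0 or volume_mL <= 0:
        raise ParameterError("dose must be >= 0 and molar mass/volume > 0")
    return dose_mg / molar_mass / volume_mL * 1000.0


def mm_absorption_flux(driving_conc_uM: float, Vmax: float, Km_mM: float,
                       PBSF: float, tsf_ex: float, tsf_ph: float,
                       inhibition_divisor: float = 1.0,
                       scale: float = 1.0) -> float:
    """Segmental Michaelis-Menten transporter flux (nmol/min).

    ``Vmax`` is per mg S9 protein and is scaled by the segment protein
    amount ``PBSF``, the regional expression scalar ``tsf_ex``, the pH
    activity scalar ``tsf_ph`` and the in-vivo scaling factor ``scale``;
    competitive inhibition divides Vmax by ``inhibition_divisor``.
    """
    if Km_mM <= 0:
        raise ParameterError("Km must be > 0")
    if min(Vmax, PBSF, tsf_ex, tsf_ph, inhibition_divisor, scale) < 0:
        raise ParameterError("flux parameters must be >= 0")
    c = max(driving_conc_uM, 0.0)
    km_uM = Km_mM * 1000.0
    return PBSF * scale * (Vmax / inhibition_divisor) * c / (km_uM + c) * tsf_ex * tsf_ph


def _conc(y: np.ndarray, idx: int, volume: float) -> float:
    """Concentration with non-negativity flooring at flux evaluation."""
    a = y[idx]
    return a / volume if a > 0.0 else 0.0


# ---------------------------------------------------------------------------
# gut
# ---------------------------------------------------------------------------


def victim_gut_rhs(y, dy, L: StateLayout, profile: DrugProfile,
                   geom: GutGeometry, phys: PhysiologyTable,
                   inh: InhibitionContext = NO_INHIBITION,
                   gut_flux_driving: str = "lumen") -> None:
    """Stomach + lumen transit with passive and saturable (OCT3/PMAT) uptake.

    The Michaelis-Menten terms are driven by the lumen concentration by
    default (``gut_flux_driving='lumen'``); ``'enterocyte'`` drives them by
    the enterocyte concentration divided by the gut partition ratio instead.
    Only OCT3 uptake is subject to perpetrator inhibition.
    """
    A0 = max(y[L["stomach"]], 0.0)
    dy[L["stomach"]] -= geom.K_t0 * A0
    upstream = geom.K_t0 * A0

    c_art = _conc(y, L["art"], phys.V_art)
    tsf_oct3 = geom.tsf_ph("OCT3")
    tsf_pmat = geom.tsf_ph("PMAT")

    for i, seg in enumerate(ABSORBING_SEGMENTS):
        il, ig = L[f"lumen_{seg}"], L[f"gw_{seg}"]
        A = max(y[il], 0.0)
        transit_out = geom.K_t[i] * A
        passive = geom.passive_fraction * profile.ka(geom.radius_cm[i]) * A

        if gut_flux_driving == "lumen":
            driving = _conc(y, il, geom.V_lumen[i])
        elif gut_flux_driving == "enterocyte":
            driving = _conc(y, ig, phys.V_gw[i]) / profile.K_gb
        else:
            raise ParameterError(f"unknown gut_flux_driving {gut_flux_driving!r}")

        f_oct3 = f_pmat = 0.0
        if profile.Vmax_OCT3 is not None:
            div = competitive_factor(inh.lumen[i], inh.Ki_OCT3)
            f_oct3 = mm_absorption_flux(driving, profile.Vmax_OCT3,
                                        profile.Km_OCT3, geom.PBSF[i],
                                        geom.tsf_ex_oct3[i], tsf_oct3[i],
                                        div, profile.sf_OCT3)
        if profile.Vmax_PMAT is not None:
            f_pmat = mm_absorption_flux(driving, profile.Vmax_PMAT,
                                        profile.Km_PMAT, geom.PBSF[i],
                                        1.0, tsf_pmat[i],
                                        1.0, profile.sf_PMAT)

        absorbed = passive + f_oct3 + f_pmat
        dy[il] += upstream - transit_out - absorbed
        c_gw = _conc(y, ig, phys.V_gw[i])
        outflow = phys.Q_gw[i] * c_gw / profile.K_gb
        dy[ig] += absorbed + phys.Q_gw[i] * c_art - outflow
        dy[L["art"]] -= phys.Q_gw[i] * c_art
        upstream = transit_out

    # material leaving the ileum enters the non-absorbing caecum/colon sink
    dy[L["fecal_cum"]] += upstream


def perpetrator_gut_rhs(y, dy, L: StateLayout, profile: DrugProfile,
                        geom: GutGeometry, phys: PhysiologyTable) -> None:
    """Linear transit chain with first-order absorption (no saturation)."""
    A0 = max(y[L["stomach"]], 0.0)
    dy[L["stomach"]] -= geom.K_t0 * A0
    upstream = geom.K_t0 * A0
    c_art = _conc(y, L["art"], phys.V_art)
    for i, seg in enumerate(ABSORBING_SEGMENTS):
        il, ig = L[f"lumen_{seg}"], L[f"gw_{seg}"]
        A = max(y[il], 0.0)
        transit_out = geom.K_t[i] * A
        absorbed = profile.ka(geom.radius_cm[i]) * A
        dy[il] += upstream - transit_out - absorbed
        c_gw = _conc(y, ig, phys.V_gw[i])
        dy[ig] += absorbed + phys.Q_gw[i] * c_art - phys.Q_gw[i] * c_gw / profile.K_gb
        dy[L["art"]] -= phys.Q_gw[i] * c_art
        upstream = transit_out
    dy[L["fecal_cum"]] += upstream


# ---------------------------------------------------------------------------
# liver (and spleen, which drains into it)
# ---------------------------------------------------------------------------


def _portal_inflow(y, L, profile, phys) -> float:
    """Drug flux entering the liver: hepatic artery + gut wall + spleen."""
    c_art = _conc(y, L["art"], phys.V_art)
    inflow = phys.Q_ha * c_art
    for i, seg in enumerate(ABSORBING_SEGMENTS):
        inflow += phys.Q_gw[i] * _conc(y, L[f"gw_{seg}"], phys.V_gw[i]) / profile.K_gb
    inflow += phys.Q_sp * _conc(y, L["spleen"], phys.V_sp) / profile.K_spb
    return inflow


def _spleen_rhs(y, dy, L, profile, phys) -> None:
    c_art = _conc(y, L["art"], phys.V_art)
    c_sp = _conc(y, L["spleen"], phys.V_sp)
    dy[L["spleen"]] += phys.Q_sp * (c_art - c_sp / profile.K_spb)
    dy[L["art"]] -= phys.Q_sp * c_art


def victim_liver_rhs(y, dy, L: StateLayout, profile: DrugProfile,
                     phys: PhysiologyTable,
                     inh: InhibitionContext = NO_INHIBITION) -> None:
    """Permeability-limited liver: sinusoidal blood + hepatocytes.

    OCT1-mediated uptake (inhibitable) and passive bidirectional exchange
    connect the two; metabolism removes unbound drug from hepatocytes.
    """
    ib, ic = L["liver_blood"], L["liver_cell"]
    c_hb = _conc(y, ib, phys.V_hb)
    c_hc = _conc(y, ic, phys.V_hc)
    c_art = _conc(y, L["art"], phys.V_art)

    _spleen_rhs(y, dy, L, profile, phys)
    inflow = _portal_inflow(y, L, profile, phys)
    dy[L["art"]] -= phys.Q_ha * c_art
    dy[ib] += inflow - phys.Q_L * c_hb
    dy[L["ven"]] += phys.Q_L * c_hb

    div = competitive_factor(inh.liver_blood_unbound, inh.Ki_OCT1)
    uptake = (profile.CLint_up_OCT1 / div) * profile.f_ub * c_hb
    passive = profile.f_ub * profile.CLint_pd * (c_hc / profile.K_hb - c_hb)
    metab = profile.f_ub * profile.CLint_met * c_hc / profile.K_hb

    dy[ib] += -uptake + passive
    dy[ic] += uptake - passive - metab
    dy[L["met_cum"]] += metab


def well_stirred_liver_rhs(y, dy, L: StateLayout, profile: DrugProfile,
                           phys: PhysiologyTable) -> None:
    """Single well-stirred liver compartment with metabolic elimination."""
    ih = L["liver"]
    c_h = _conc(y, ih, phys.V_h)
    c_art = _conc(y, L["art"], phys.V_art)

    _spleen_rhs(y, dy, L, profile, phys)
    inflow = _portal_inflow(y, L, profile, phys)
    dy[L["art"]] -= phys.Q_ha * c_art
    metab = profile.f_ub * profile.CLint_met * c_h / profile.K_hb
    dy[ih] += inflow - phys.Q_L * c_h / profile.K_hb - metab
    dy[L["ven"]] += phys.Q_L * c_h / profile.K_hb
    dy[L["met_cum"]] += metab


# ---------------------------------------------------------------------------
# kidney
# ---------------------------------------------------------------------------


def victim_kidney_rhs(y, dy, L: StateLayout, profile: DrugProfile,
                      phys: PhysiologyTable,
                      inh: InhibitionContext = NO_INHIBITION) -> None:
    """Serial OCT2 (basolateral) / MATE (apical) renal secretion model.

    Blood -> tubule uptake (OCT2, RAF-scaled, plus any parallel OAT3 route)
    is inhibited by the perpetrator's unbound renal-blood concentration and
    tubule -> urine MATE efflux (RAF-scaled) by its intracellular
    concentration.  The un-scaled basolateral OCT2 backflux returning drug
    to blood is not inhibited: competitive Ki values describe binding at
    the extracellular substrate face, and no cytoplasmic-face affinity is
    available (see docs/methods.md).  Filtration (f_ub*GFR) passes directly
    from renal blood to urine.
    """
    ib, ie = L["kidney_blood"], L["tubule"]
    c_rb = _conc(y, ib, phys.V_rb)
    c_re = _conc(y, ie, phys.V_re)
    c_art = _conc(y, L["art"], phys.V_art)

    dy[ib] += phys.Q_r * (c_art - c_rb)
    dy[L["art"]] -= phys.Q_r * c_art
    dy[L["ven"]] += phys.Q_r * c_rb

    div_up = competitive_factor(inh.kidney_blood_unbound, inh.Ki_OCT2)
    div_mate = competitive_factor(inh.tubule_unbound, inh.Ki_MATE)

    uptake = (phys.RAF * profile.CLint_up_OCT2 / div_up) * profile.f_ub * c_rb
    uptake += phys.RAF * profile.CLint_up_OAT3 * profile.f_ub * c_rb
    backflux = profile.CLint_up_OCT2 * profile.f_ub * c_re / profile.K_rb
    secretion = (phys.RAF * profile.CLint_eff_MATE / div_mate) * profile.f_ub \
        * c_re / profile.K_rb
    filtration = profile.f_ub * phys.GFR * c_rb

    dy[ib] += -uptake + backflux - filtration
    dy[ie] += uptake - backflux - secretion
    dy[L["urine_cum"]] += filtration + secretion


def well_stirred_kidney_rhs(y, dy, L: StateLayout, profile: DrugProfile,
                            phys: PhysiologyTable) -> None:
    """Single well-stirred kidney compartment eliminating to urine."""
    ir = L["kidney"]
    c_r = _conc(y, ir, phys.V_r)
    c_art = _conc(y, L["art"], phys.V_art)
    excretion = profile.f_ub * profile.CLint_renal * c_r / profile.K_rb
    dy[ir] += phys.Q_r * c_art - phys.Q_r * c_r / profile.K_rb - excretion
    dy[L["art"]] -= phys.Q_r * c_art
    dy[L["ven"]] += phys.Q_r * c_r / profile.K_rb
    dy[L["urine_cum"]] += excretion


# ---------------------------------------------------------------------------
# circulation
# ---------------------------------------------------------------------------


def circulation_rhs(y, dy, L: StateLayout, profile: DrugProfile,
                    phys: PhysiologyTable) -> None:
    """Lung between venous and arterial pools; flow-limited peripheral tissues."""
    c_art = _conc(y, L["art"], phys.V_art)
    c_ven = _conc(y, L["ven"], phys.V_ven)
    c_lu = _conc(y, L["lung"], phys.V_lu)

    dy[L["ven"]] -= phys.Q_total * c_ven
    dy[L["lung"]] += phys.Q_total * (c_ven - c_lu / profile.K_lub)
    dy[L["art"]] += phys.Q_total * c_lu / profile.K_lub

    for t in PERIPHERAL_TISSUES:
        q = phys.Q_per[t]
        c_t = _conc(y, L[t], phys.V_per[t])
        dy[L[t]] += q * (c_art - c_t / profile.K_per[t])
        dy[L["art"]] -= q * c_art
        dy[L["ven"]] += q * c_t / profile.K_per[t]


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def build_inhibition_context(y_perp, L_perp: StateLayout,
                             perp: DrugProfile, phys: PhysiologyTable,
                             geom: GutGeometry) -> InhibitionContext:
    """Perpetrator exposure at the victim's transporters, from its state.

    For a well-stirred perpetrator liver/kidney the organ blood
    concentration is approximated by the tissue concentration divided by
    the tissue partition ratio.
    """
    lumen = tuple(_conc(y_perp, L_perp[f"lumen_{s}"], geom.V_lumen[i])
                  for i, s in enumerate(ABSORBING_SEGMENTS))
    if perp.liver_model == TRANSPORTER_EXPLICIT:
        liver_b = perp.f_ub * _conc(y_perp, L_perp["liver_blood"], phys.V_hb)
    else:
        liver_b = perp.f_ub * _conc(y_perp, L_perp["liver"], phys.V_h) / perp.K_hb
    if perp.kidney_model == TRANSPORTER_EXPLICIT:
        kidney_b = perp.f_ub * _conc(y_perp, L_perp["kidney_blood"], phys.V_rb)
        tubule = perp.f_ub * _conc(y_perp, L_perp["tubule"], phys.V_re)
    else:
        kidney_b = perp.f_ub * _conc(y_perp, L_perp["kidney"], phys.V_r) / perp.K_rb
        tubule = kidney_b
    return InhibitionContext(lumen=lumen, liver_blood_unbound=liver_b,
                             kidney_blood_unbound=kidney_b,
                             tubule_unbound=tubule,
                             Ki_OCT1=perp.Ki_OCT1, Ki_OCT2=perp.Ki_OCT2,
                             Ki_OCT3=perp.Ki_OCT3, Ki_MATE=perp.Ki_MATE)


def drug_rhs(y, dy, L: StateLayout, profile: DrugProfile,
             phys: PhysiologyTable, geom: GutGeometry,
             inh: InhibitionContext = NO_INHIBITION, *,
             victim: bool = True, gut_flux_driving: str = "lumen") -> None:
    """Full single-drug derivative: gut + liver + kidney + circulation."""
    if victim and profile.has_mm_uptake:
        victim_gut_rhs(y, dy, L, profile, geom, phys, inh, gut_flux_driving)
    else:
        perpetrator_gut_rhs(y, dy, L, profile, geom, phys)
    if profile.liver_model == TRANSPORTER_EXPLICIT:
        victim_liver_rhs(y, dy, L, profile, phys, inh)
    else:
        well_stirred_liver_rhs(y, dy, L, profile, phys)
    if profile.kidney_model == TRANSPORTER_EXPLICIT:
        victim_kidney_rhs(y, dy, L, profile, phys, inh)
    else:
        well_stirred_kidney_rhs(y, dy, L, profile, phys)
    circulation_rhs(y, dy, L, profile, phys)
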