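"""Organ flux primitives and right-hand-side conservation properties."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import metpbpk as m
from metpbpk import organs
from metpbpk.organs import (NO_INHIBITION, InhibitionContext, StateLayout,
                            competitive_factor, lumen_screening_conc,
                            mm_absorption_flux)
from metpbpk.parameters import ParameterError


class TestCompetitiveFactor:
    def test_no_inhibitor(self):
        assert competitive_factor(0.0, 10.0) == 1.0

    def test_half_maximal_at_ki(self):
        assert competitive_factor(10.0, 10.0) == 2.0

    def test_absent_ki_means_unity(self):
        assert competitive_factor(1e9, None) == 1.0

    def test_cimetidine_luminal_screen(self):
        # 400 mg in 250 mL (6.34 mM) against the OCT3 inhibition constant
        conc_uM = lumen_screening_conc(400.0, 252.34) * 1000.0
        assert competitive_factor(conc_uM, 45.7) == pytest.approx(139.7, abs=0.5)

    def test_nonpositive_ki_rejected(self):
        with pytest.raises(ParameterError):
            competitive_factor(1.0, 0.0)


class TestLumenScreening:
    @pytest.mark.parametrize("dose, mm, expected", [
        (400.0, 252.34, 6.34),     # cimetidine
        (180.0, 454.6, 1.58),      # verapamil
        (200.0, 290.32, 2.76),     # trimethoprim
        (0.0, 252.34, 0.0),
    ])
    def test_values(self, dose, mm, expected):
        assert lumen_screening_conc(dose, mm) == pytest.approx(expected, abs=0.01)

    def test_bad_molar_mass(self):
        with pytest.raises(ParameterError):
            lumen_screening_conc(100.0, 0.0)


class TestMMFlux:
    def test_saturation_asymptote(self):
        flux = mm_absorption_flux(1e12, 12.08, 2.46, 14465.81, 1.0, 0.74, 2.0)
        assert flux == pytest.approx(14465.81 * 12.08 * 0.74 / 2.0, rel=1e-6)

    def test_half_saturation_at_km(self):
        # jejunal OCT3 flux at C = Km is half the saturated flux
        c = 2.46 * 1000.0  # Km in uM
        flux = mm_absorption_flux(c, 12.08, 2.46, 14465.81, 1.0, 0.74)
        assert flux == pytest.approx(0.5 * 14465.81 * 12.08 * 0.74, rel=1e-12)

    def test_negative_conc_floored(self):
        assert mm_absorption_flux(-5.0, 12.08, 2.46, 100.0, 1.0, 1.0) == 0.0

    def test_bad_km(self):
        with pytest.raises(ParameterError):
            mm_absorption_flux(1.0, 1.0, 0.0, 1.0, 1.0, 1.0)


def _rhs(y, profile, phys, geom, inh=NO_INHIBITION, victim=True):
    L = StateLayout(profile)
    dy = np.zeros(L.n)
    organs.drug_rhs(y, dy, L, profile, phys, geom, inh, victim=victim)
    return L, dy


class TestConservation:
    """Every flux leaves one compartment and enters another (or a sink)."""

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_victim_rhs_conserves_mass(self, seed, metformin, phys, geom):
        rng = np.random.default_rng(seed)
        L = StateLayout(metformin)
        y = rng.uniform(0.0, 1e5, size=L.n)
        _, dy = _rhs(y, metformin, phys, geom)
        assert abs(dy.sum()) < 1e-7 * np.abs(dy).max()

    def test_perpetrator_rhs_conserves_mass(self, cimetidine, phys, geom):
        rng = np.random.default_rng(3)
        L = StateLayout(cimetidine)
        y = rng.uniform(0.0, 1e5, size=L.n)
        _, dy = _rhs(y, cimetidine, phys, geom, victim=False)
        assert abs(dy.sum()) < 1e-7 * np.abs(dy).max()

    def test_transporterless_gut_is_pure_transit(self, metformin, phys, geom):
        prof = dataclasses.replace(metformin, Vmax_OCT3=None, Km_OCT3=None,
                                   Vmax_PMAT=None, Km_PMAT=None,
                                   P_eff=None, ka_fixed=0.0)
        L = StateLayout(prof)
        y = L.zeros()
        y[L["stomach"]] = 1e4
        y[L["lumen_jejunum"]] = 5e3
        dy = np.zeros(L.n)
        organs.victim_gut_rhs(y, dy, L, prof, geom, phys)
        gut = [L["stomach"]] + [L[f"lumen_{s}"] for s in
                                ("duodenum", "jejunum", "ileum")] + [L["fecal_cum"]]
        assert abs(sum(dy[i] for i in gut)) < 1e-12
        assert all(dy[L[f"gw_{s}"]] == 0.0 for s in ("duodenum", "jejunum", "ileum"))


class TestInhibitionWiring:
    def test_zero_conc_context_equals_no_inhibition(self, metformin, cimetidine,
                                                    phys, geom):
        rng = np.random.default_rng(1)
        L = StateLayout(metformin)
        y = rng.uniform(0.0, 1e4, size=L.n)
        ctx = InhibitionContext(Ki_OCT1=cimetidine.Ki_OCT1,
                                Ki_OCT2=cimetidine.Ki_OCT2,
                                Ki_OCT3=cimetidine.Ki_OCT3,
                                Ki_MATE=cimetidine.Ki_MATE)
        _, dy0 = _rhs(y, metformin, phys, geom, NO_INHIBITION)
        _, dy1 = _rhs(y, metformin, phys, geom, ctx)
        np.testing.assert_allclose(dy0, dy1, rtol=1e-14)

    def test_oct1_inhibitor_at_ki_halves_uptake(self, metformin, phys, geom):
        L = StateLayout(metformin)
        y = L.zeros()
        y[L["liver_blood"]] = 1000.0
        base = np.zeros(L.n)
        organs.victim_liver_rhs(y, base, L, metformin, phys, NO_INHIBITION)
        ctx = InhibitionContext(liver_blood_unbound=101.0, Ki_OCT1=101.0)
        inhib = np.zeros(L.n)
        organs.victim_liver_rhs(y, inhib, L, metformin, phys, ctx)
        c_hb = y[L["liver_blood"]] / phys.V_hb
        uptake_base = metformin.CLint_up_OCT1 * metformin.f_ub * c_hb
        assert base[L["liver_cell"]] - inhib[L["liver_cell"]] == pytest.approx(
            uptake_base / 2.0, rel=1e-12)

    def test_mate_inhibitor_at_ki_halves_secretion(self, metformin, phys, geom):
        L = StateLayout(metformin)
        y = L.zeros()
        y[L["tubule"]] = 1000.0   # only tubule loaded: urine flux = MATE efflux
        base = np.zeros(L.n)
        organs.victim_kidney_rhs(y, base, L, metformin, phys, NO_INHIBITION)
        ctx = InhibitionContext(tubule_unbound=0.65, Ki_MATE=0.65)
        inhib = np.zeros(L.n)
        organs.victim_kidney_rhs(y, inhib, L, metformin, phys, ctx)
        assert inhib[L["urine_cum"]] == pytest.approx(
            base[L["urine_cum"]] / 2.0, rel=1e-12)

    def test_backflux_is_not_inhibited(self, metformin, phys):
        """Intracellular perpetrator blocks MATE but not the OCT2 backflux."""
        L = StateLayout(metformin)
        y = L.zeros()
        y[L["tubule"]] = 1000.0
        ctx = InhibitionContext(tubule_unbound=1e9, Ki_OCT2=2.97, Ki_MATE=0.65)
        dy = np.zeros(L.n)
        organs.victim_kidney_rhs(y, dy, L, metformin, phys, ctx)
        c_re = y[L["tubule"]] / phys.V_re
        backflux = metformin.CLint_up_OCT2 * metformin.f_ub * c_re / metformin.K_rb
        assert dy[L["kidney_blood"]] == pytest.approx(backflux, rel=1e-9)
        uninhibited = phys.RAF * metformin.CLint_eff_MATE * metformin.f_ub \
            * c_re / metformin.K_rb
        assert dy[L["urine_cum"]] < 1e-8 * uninhibited


class TestLiverSteadyState:
    def test_cell_blood_ratio_without_metabolism(self, metformin, phys):
        """With CLint_met = 0 the hepatocyte/blood concentration ratio at
        steady state follows from uptake/passive balance."""
        prof = dataclasses.replace(metformin, CLint_met=0.0, CLint_pd=50.0)
        L = StateLayout(prof)
        c_hb = 5.0
        ratio = prof.K_hb * (prof.CLint_up_OCT1 + prof.CLint_pd) / prof.CLint_pd
        y = L.zeros()
        y[L["liver_blood"]] = c_hb * phys.V_hb
        y[L["liver_cell"]] = c_hb * ratio * phys.V_hc
        dy = np.zeros(L.n)
        organs.victim_liver_rhs(y, dy, L, prof, phys, NO_INHIBITION)
        # cell compartment is at equilibrium (blood still flows out)
        assert dy[L["liver_cell"]] == pytest.approx(0.0, abs=1e-9)

    def test_uptake_limited_elimination_rate(self, metformin, phys):
        """With negligible passive exchange, hepatic elimination equals the
        OCT1 uptake rate once the cell is at quasi-steady state."""
        prof = metformin  # CLint_pd is ~1 mL/min in the fixture
        L = StateLayout(prof)
        c_hb = 2.0
        # quasi-steady cell concentration from the cell balance
        c_hc_over_k = c_hb * (prof.CLint_up_OCT1 + prof.CLint_pd) \
            / (prof.CLint_pd + prof.CLint_met)
        y = L.zeros()
        y[L["liver_blood"]] = c_hb * phys.V_hb
        y[L["liver_cell"]] = c_hc_over_k * prof.K_hb * phys.V_hc
        dy = np.zeros(L.n)
        organs.victim_liver_rhs(y, dy, L, prof, phys, NO_INHIBITION)
        expected = prof.f_ub * prof.CLint_met * c_hc_over_k
        assert dy[L["met_cum"]] == pytest.approx(expected, rel=1e-12)
        assert dy[L["liver_cell"]] == pytest.approx(0.0, abs=1e-9)


class TestCirculation:
    def test_partition_equilibrium_is_stationary(self, phys, geom):
        """With all clearances zero, concentrations proportional to the
        tissue partition ratios are a fixed point of the circulation."""
        prof = m.DrugProfile(name="inert", molar_mass=100.0, f_ub=1.0, R_b=1.0,
                             ka_fixed=0.0)
        L = StateLayout(prof)
        c = 3.0
        y = L.zeros()
        y[L["art"]] = c * phys.V_art
        y[L["ven"]] = c * phys.V_ven
        y[L["lung"]] = c * prof.K_lub * phys.V_lu
        y[L["spleen"]] = c * prof.K_spb * phys.V_sp
        y[L["liver"]] = c * prof.K_hb * phys.V_h
        y[L["kidney"]] = c * prof.K_rb * phys.V_r
        for i, s in enumerate(("duodenum", "jejunum", "ileum")):
            y[L[f"gw_{s}"]] = c * prof.K_gb * phys.V_gw[i]
        for t in ("heart", "brain", "muscle", "adipose", "skin", "rest"):
            y[L[t]] = c * prof.K_per[t] * phys.V_per[t]
        dy = np.zeros(L.n)
        organs.drug_rhs(y, dy, L, prof, phys, geom, victim=False)
        assert np.abs(dy).max() < 1e-8 * c * phys.V_ven

    def test_lung_derivative_matches_flow_balance(self, metformin, phys, geom):
        L = StateLayout(metformin)
        rng = np.random.default_rng(0)
        y = rng.uniform(0, 1e4, L.n)
        dy = np.zeros(L.n)
        organs.circulation_rhs(y, dy, L, metformin, phys)
        c_ven = y[L["ven"]] / phys.V_ven
        c_lu = y[L["lung"]] / phys.V_lu
        assert dy[L["lung"]] == pytest.approx(
            phys.Q_total * (c_ven - c_lu / metformin.K_lub), rel=1e-12)
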