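"""Synthetic observed datasets, virtual populations and parameter recovery."""

import dataclasses

import numpy as np
import pytest

import metpbpk as m
from metpbpk import io as mio
from metpbpk import synthetic as ms
from metpbpk import validation as mv
from metpbpk.parameters import DoseRegimen


@pytest.fixture(scope="module")
def reg500():
    return DoseRegimen("metformin", 500.0)


@pytest.fixture(scope="module")
def gen_options():
    return m.SolverOptions(rtol=1e-6, atol=1e-8, grid_step_min=5.0)


class TestGenerateObserved:
    def test_noiseless_matches_model(self, metformin, reg500, phys, geom,
                                     gen_options):
        ds = ms.generate_observed(metformin, reg500, phys, geom,
                                  residual_cv=0.0, seed=0, options=gen_options)
        res = m.simulate(metformin, reg500, phys, geom, t_end_min=1440.0,
                         options=gen_options)
        expected = np.interp(ds.data["time_h"] * 60.0, res.t_min,
                             res.plasma_conc())
        np.testing.assert_allclose(ds.data["conc_ug_per_ml"], expected,
                                   rtol=1e-9)

    def test_seed_determinism(self, metformin, reg500, phys, geom, gen_options):
        a = ms.generate_observed(metformin, reg500, phys, geom,
                                 residual_cv=0.2, n_subjects=4, seed=9,
                                 options=gen_options)
        b = ms.generate_observed(metformin, reg500, phys, geom,
                                 residual_cv=0.2, n_subjects=4, seed=9,
                                 options=gen_options)
        assert a.data.equals(b.data)

    def test_empirical_cv_matches_nominal(self, metformin, reg500, phys, geom,
                                          gen_options):
        """At 20% residual CV the across-subject spread at one sampling time
        reproduces the nominal CV (single simulation, many noise draws)."""
        ds = ms.generate_observed(metformin, reg500, phys, geom,
                                  residual_cv=0.20, n_subjects=400, seed=2,
                                  options=gen_options)
        at4h = ds.data[ds.data["time_h"] == 4.0]["conc_ug_per_ml"]
        cv = at4h.std() / at4h.mean()
        assert cv == pytest.approx(0.20, abs=0.03)

    def test_truth_record_embedded(self, metformin, reg500, phys, geom,
                                   gen_options):
        ds = ms.generate_observed(metformin, reg500, phys, geom,
                                  residual_cv=0.1, seed=0, options=gen_options)
        assert ds.truth["CLint_up_OCT2"] == metformin.CLint_up_OCT2
        assert ds.truth["sf_OCT3"] == metformin.sf_OCT3


class TestGeneratePopulation:
    def test_zero_variance_identical_subjects(self, metformin, geom):
        spec = mv.PopulationSpec(cv={}, residual_cv=0.0, n_subjects=5, seed=1)
        subjects = ms.generate_population(spec, metformin, geom)
        assert all(p == metformin for p, _ in subjects)
        assert all(g.K_t == geom.K_t for _, g in subjects)

    def test_seed_determinism(self, metformin, geom):
        spec = mv.PopulationSpec(n_subjects=6, seed=11)
        a = ms.generate_population(spec, metformin, geom)
        b = ms.generate_population(spec, metformin, geom)
        assert [p.sf_OCT3 for p, _ in a] == [p.sf_OCT3 for p, _ in b]
        assert [g.K_t0 for _, g in a] == [g.K_t0 for _, g in b]

    def test_lognormal_mean_recovers_truth(self, metformin, geom):
        """Sample mean of the log-parameters converges to the log-truth."""
        spec = mv.PopulationSpec(n_subjects=4000, seed=3)
        subjects = ms.generate_population(spec, metformin, geom)
        for name in ("sf_OCT3", "CLint_up_OCT2"):
            logs = np.log([getattr(p, name) for p, _ in subjects])
            assert logs.mean() == pytest.approx(
                np.log(getattr(metformin, name)), abs=3 * spec.omega(name) / 60)

    def test_only_the_five_random_effects_move(self, metformin, geom):
        spec = mv.PopulationSpec(n_subjects=3, seed=5)
        for p, _ in ms.generate_population(spec, metformin, geom):
            assert p.CLint_met == metformin.CLint_met
            assert p.P_eff == metformin.P_eff
            assert p.sf_PMAT == metformin.sf_PMAT


class TestCSVRoundTrip:
    def test_lossless(self, metformin, reg500, phys, geom, gen_options,
                      tmp_path):
        ds = ms.generate_observed(metformin, reg500, phys, geom,
                                  residual_cv=0.2, n_subjects=3, seed=4,
                                  options=gen_options)
        path = tmp_path / "obs.csv"
        mio.write_observed_csv(ds, path)
        back = mio.read_observed_csv(path)
        np.testing.assert_array_equal(back["conc_ug_per_ml"],
                                      ds.data["conc_ug_per_ml"])
        np.testing.assert_array_equal(back["subject"], ds.data["subject"])

    def test_malformed_header_names_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("subject,hours,conc_ug_per_ml\n1,0.5,1.0\n")
        with pytest.raises(mio.ConfigError, match="time_h"):
            mio.read_observed_csv(path)


BOUNDS = {"sf_OCT3": (0.01, 0.3), "CLint_up_OCT2": (50.0, 1500.0)}


class TestRecovery:
    def test_noiseless_fixed_point(self, metformin, reg500, phys, geom,
                                   gen_options):
        ds = ms.generate_observed(metformin, reg500, phys, geom,
                                  residual_cv=0.0, seed=0, options=gen_options)
        rec = ms.recover_parameters(ds, metformin, reg500,
                                    ["sf_OCT3", "CLint_up_OCT2"], BOUNDS,
                                    phys, geom, options=gen_options)
        assert rec.converged
        for p in rec.estimates:
            assert rec.relative_error(p) < 0.01

    def test_bias_shrinks_with_residual_noise(self, metformin, reg500, phys,
                                              geom, gen_options):
        """Recovery error is monotone over a 0 / 10% / 20% noise grid."""
        start = dataclasses.replace(metformin, sf_OCT3=metformin.sf_OCT3 * 1.6,
                                    CLint_up_OCT2=metformin.CLint_up_OCT2 * 0.6)
        errors = []
        for cv in (0.0, 0.1, 0.2):
            ds = ms.generate_observed(metformin, reg500, phys, geom,
                                      residual_cv=cv, n_subjects=12, seed=5,
                                      options=gen_options)
            rec = ms.recover_parameters(ds, start, reg500,
                                        ["sf_OCT3", "CLint_up_OCT2"], BOUNDS,
                                        phys, geom, options=gen_options)
            errors.append(max(abs(rec.estimates[p] - ds.truth[p]) / ds.truth[p]
                              for p in rec.estimates))
        assert errors[0] < 0.01
        assert errors[0] <= errors[1] <= errors[2]

    def test_serial_renal_pair_is_flat(self, metformin, reg500, phys, geom,
                                       gen_options):
        """OCT2 uptake and MATE efflux are serially redundant on plasma-only
        data: rebalancing the pair at constant secretion clearance leaves the
        objective nearly unchanged while the parameters move far."""
        ds = ms.generate_observed(metformin, reg500, phys, geom,
                                  residual_cv=0.0, seed=0, options=gen_options)
        t_obs = ds.data["time_h"].to_numpy() * 60.0
        log_obs = np.log(ds.data["conc_ug_per_ml"].to_numpy())

        def ssq(profile):
            res = m.simulate(profile, reg500, phys, geom,
                             t_end_min=float(t_obs.max()), options=gen_options)
            conc = np.interp(t_obs, res.t_min, res.plasma_conc())
            return float(np.sum((np.log(conc) - log_obs) ** 2))

        raf = phys.RAF
        U = raf * metformin.CLint_up_OCT2
        M = raf * metformin.CLint_eff_MATE
        B = metformin.CLint_up_OCT2
        sec = U * M / (B + M)           # serial secretion clearance
        oct2_doubled = 2.0 * metformin.CLint_up_OCT2
        # MATE value preserving the steady-state serial secretion clearance
        M2 = oct2_doubled * sec / (raf * oct2_doubled - sec)
        rebalanced = dataclasses.replace(metformin, CLint_up_OCT2=oct2_doubled,
                                         CLint_eff_MATE=M2 / raf)
        far = dataclasses.replace(metformin,
                                  CLint_up_OCT2=2 * metformin.CLint_up_OCT2)
        assert ssq(rebalanced) < 0.1 * ssq(far)
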