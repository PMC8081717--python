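"""New-location prediction: predictable functions, SEPV/SEPD identities,
prediction intervals, affine invariance of random-coefficient models, and
zone borrowing."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import zonemet as zm
from zonemet.predict import build_predictable_function, prediction_interval


@pytest.fixture(scope="module")
def rc_met():
    G_gz = np.array([[200.0, 50.0, -10.0],
                     [50.0, 150.0, 30.0],
                     [-10.0, 30.0, 60.0]])
    cfg = zm.SimulationConfig(
        seed=11, zones={"North": 6, "Middle": 6, "South": 6},
        n_new={"North": 1, "South": 1}, n_genotypes=8, block_size=4, G_gz=G_gz)
    ds, cov, _ = zm.simulate_met(cfg)
    new_cov, _ = zm.simulate_new_locations(cfg)
    allcov = zm.merged_covariates(cov, new_cov)
    stage2 = zm.assemble_stage2(zm.run_stage1(ds))
    return {"stage2": stage2, "covariates": allcov}


def _fit(rc_met, model_id, cov_spec=None, rc_structure="us3"):
    spec = zm.make_model(model_id, cov_spec, rc_structure)
    return zm.fit_reml(zm.build_stage2_design(spec, rc_met["stage2"],
                                              rc_met["covariates"]))


class TestPredictionInterval:
    def test_normal_quantile(self):
        lo, hi = prediction_interval(100.0, 10.0, 0.05)
        assert lo == pytest.approx(100 - 1.959964 * 10, abs=1e-3)
        assert hi == pytest.approx(100 + 1.959964 * 10, abs=1e-3)

    def test_standard_case(self):
        lo, hi = prediction_interval(0.0, 1.0, 0.05)
        assert lo == pytest.approx(-1.959964, abs=1e-5)
        assert hi == pytest.approx(1.959964, abs=1e-5)

    def test_degenerate_se(self):
        assert prediction_interval(5.0, 0.0, 0.05) == (5.0, 5.0)

    def test_width_shrinks_as_alpha_grows(self):
        widths = [prediction_interval(0, 1, a)[1] for a in (0.05, 0.5, 0.999)]
        assert widths[0] > widths[1] > widths[2]
        assert widths[2] == pytest.approx(0.0, abs=2e-3)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.3, 2.0])
    def test_invalid_alpha(self, alpha):
        with pytest.raises(ValueError):
            prediction_interval(0.0, 1.0, alpha)


class TestPredictableFunction:
    def test_rg1_unobservable_variance_is_zone_sum(self, rg1_fit, small_met):
        fit = rg1_fit
        pf = build_predictable_function(fit, fit.model.genotypes[0], "South", None)
        expect = (fit.variance("location", "South")
                  + fit.variance("gxl", "South"))
        assert pf.M0 @ pf.G0 @ pf.M0 == pytest.approx(expect, rel=1e-12)

    def test_fg_model_has_empty_M(self, rc_met):
        fit = _fit(rc_met, "FG1")
        pf = build_predictable_function(fit, fit.model.genotypes[0], "South", None)
        assert not pf.M.any()
        # genotype effects enter through K instead
        assert pf.K[fit.fixed_index(("genotype", fit.model.genotypes[0]))] == 1.0
        assert pf.K[fit.fixed_index(("gxz", fit.model.genotypes[0], "South"))] == 1.0

    def test_rc_triplet_weights_at_zero_covariate(self, rc_met, clay_spec):
        fit = _fit(rc_met, "RC2", clay_spec)
        g = fit.model.genotypes[0]
        pf = build_predictable_function(fit, g, "South", 0.0)
        assert pf.M[fit.random_index(("rc_gxz", g, "South", 0))] == 1.0
        assert pf.M[fit.random_index(("rc_gxz", g, "South", 1))] == 0.0
        assert pf.M[fit.random_index(("rc_gxz", g, "South", 2))] == 0.0

    def test_unknown_zone_rejected(self, rg1_fit, small_met):
        cov = small_met["covariates"]
        bad = zm.CovariateTable(cov.table.assign(zone="Atlantis").reset_index())
        with pytest.raises(ValueError, match="zone"):
            zm.predict_new_location(rg1_fit, bad, bad.new_locations[0])


class TestSepvSepd:
    def test_sepv_identity(self, rg1_fit, small_met):
        # SEPV^2 - pev(eta_hat) equals the unobservable-part variance
        cov = small_met["covariates"]
        loc = cov.new_locations[0]
        zone = cov.zone_of(loc)
        pred = zm.predict_new_location(rg1_fit, cov, loc)
        g0 = (rg1_fit.variance("location", zone)
              + rg1_fit.variance("gxl", zone))
        for _, row in pred.table.iterrows():
            pf = build_predictable_function(rg1_fit, row["genotype"], zone, None)
            var_eta = zm.pev(rg1_fit, pf.K, pf.M)
            assert row["sepv"] ** 2 == pytest.approx(var_eta + g0, rel=1e-10)

    def test_pythagorean_arithmetic(self):
        # pev = 9 and unobservable variance 16 compose to SEPV = 5
        assert np.sqrt(9.0 + 16.0) == pytest.approx(5.0)

    def test_sepd_identity_and_antisymmetry(self, rg1_fit, small_met):
        cov = small_met["covariates"]
        loc = cov.new_locations[1]
        zone = cov.zone_of(loc)
        pairs = zm.pairwise_differences(rg1_fit, cov, loc)
        s2gl = rg1_fit.variance("gxl", zone)
        genos = rg1_fit.model.genotypes
        assert len(pairs.table) == len(genos) * (len(genos) - 1) // 2
        # self-pairs excluded
        assert (pairs.table["genotype_i"] != pairs.table["genotype_j"]).all()
        for _, row in pairs.table.iterrows():
            pf_i = build_predictable_function(rg1_fit, row["genotype_i"], zone, None)
            pf_j = build_predictable_function(rg1_fit, row["genotype_j"], zone, None)
            vdiff = zm.pev(rg1_fit, pf_i.K - pf_j.K, pf_i.M - pf_j.M)
            assert row["sepd"] ** 2 - vdiff == pytest.approx(2 * s2gl, rel=1e-8)
            # reversed contrast gives the negated difference
            rev = float((pf_j.K - pf_i.K) @ rg1_fit.beta
                        + (pf_j.M - pf_i.M) @ rg1_fit.u)
            assert rev == pytest.approx(-row["diff"], rel=1e-10)

    def test_sepd_brute_force_decomposition(self, rg1_fit, small_met):
        """The SEPD must match the error sd of the *full* predictable
        difference w_i - w_j, including both genotypes' unobservable
        new-location interaction effects, derived from the joint MVN."""
        cov = small_met["covariates"]
        loc = cov.new_locations[0]
        zone = cov.zone_of(loc)
        pairs = zm.pairwise_differences(rg1_fit, cov, loc)
        row = pairs.table.iloc[0]
        pf_i = build_predictable_function(rg1_fit, row["genotype_i"], zone, None)
        pf_j = build_predictable_function(rg1_fit, row["genotype_j"], zone, None)
        # w_i - w_j = (eta_i - eta_j) + (gl_i0 - gl_j0); the location main
        # effect cancels, the two gl effects are iid with variance s2gl
        # and independent of the data
        vdiff = zm.pev(rg1_fit, pf_i.K - pf_j.K, pf_i.M - pf_j.M)
        s2gl = rg1_fit.variance("gxl", zone)
        full_var = vdiff + s2gl + s2gl
        assert row["sepd"] == pytest.approx(np.sqrt(full_var), rel=1e-12)


class TestAffineInvariance:
    def test_rc2_invariant_under_shift_and_scale(self, rc_met):
        base = zm.CovariateSpec("clay", "shift_scale", 40.0, 10.0)
        moved = zm.CovariateSpec("clay", "shift_scale", 55.0, 25.0)
        f1, f2 = _fit(rc_met, "RC2", base), _fit(rc_met, "RC2", moved)
        cov = rc_met["covariates"]
        for loc in cov.new_locations:
            p1 = zm.predict_new_location(f1, cov, loc).table
            p2 = zm.predict_new_location(f2, cov, loc).table
            np.testing.assert_allclose(p1["eta"], p2["eta"], rtol=1e-3)
            np.testing.assert_allclose(p1["sepv"], p2["sepv"], rtol=1e-3)
            d1 = zm.pairwise_differences(f1, cov, loc).table
            d2 = zm.pairwise_differences(f2, cov, loc).table
            np.testing.assert_allclose(d1["sepd"], d2["sepd"], rtol=1e-3)

    def test_diagonal_rc_scale_invariant_translation_not(self, rc_met):
        base = zm.CovariateSpec("clay", "shift_scale", 40.0, 10.0)
        scaled = zm.CovariateSpec("clay", "shift_scale", 40.0, 25.0)
        shifted = zm.CovariateSpec("clay", "shift_scale", 55.0, 10.0)
        f0 = _fit(rc_met, "RC2", base, rc_structure="diag3")
        fs = _fit(rc_met, "RC2", scaled, rc_structure="diag3")
        ft = _fit(rc_met, "RC2", shifted, rc_structure="diag3")
        cov = rc_met["covariates"]
        loc = cov.new_locations[0]
        p0 = zm.predict_new_location(f0, cov, loc).table
        ps = zm.predict_new_location(fs, cov, loc).table
        pt = zm.predict_new_location(ft, cov, loc).table
        np.testing.assert_allclose(p0["sepv"], ps["sepv"], rtol=1e-3)
        shift = np.max(np.abs(pt["sepv"] - p0["sepv"]) / p0["sepv"])
        assert shift > 1e-2  # translation breaks the diagonal restriction


class TestZoneBorrowing:
    def test_rg_predictions_respond_to_other_zones_fg_do_not(self, small_met):
        ds = small_met["dataset"]
        cov = small_met["covariates"]
        # perturb one genotype's Middle-zone yields: the random genotype
        # main effect carries this across zones, whereas the saturated
        # fixed genotype x zone structure keeps zones separate (a constant
        # zone-wide shift would be absorbed by the zone effect in both)
        plots = ds.plots.copy()
        g0 = sorted(plots["genotype"].unique())[0]
        mask = (plots["zone"] == "Middle") & (plots["genotype"] == g0)
        plots.loc[mask, "yield"] += 80.0
        ds_pert = zm.Dataset(plots)
        loc = [l for l in cov.new_locations if cov.zone_of(l) == "South"][0]
        etas = {}
        for did, d in (("base", ds), ("pert", ds_pert)):
            stage2 = zm.assemble_stage2(zm.run_stage1(d))
            for mid in ("RG1", "FG1"):
                fit = zm.fit_reml(zm.build_stage2_design(zm.make_model(mid),
                                                         stage2, cov))
                etas[(mid, did)] = zm.predict_new_location(
                    fit, cov, loc).table["eta"].to_numpy()
        rg_shift = np.max(np.abs(etas[("RG1", "pert")] - etas[("RG1", "base")]))
        fg_shift = np.max(np.abs(etas[("FG1", "pert")] - etas[("FG1", "base")]))
        assert rg_shift > 1e-3          # BLUP borrows strength across zones
        assert fg_shift < 1e-6          # fixed zone-specific means do not
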