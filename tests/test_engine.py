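"""REML engine: closed-form oracles, MME identities, prediction-error
variances against an independent MVN propagation, and invariance
properties."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.linalg as sla

import zonemet as zm
from zonemet.engine import (EstimabilityError, reml_deviance,
                            reml_deviance_and_grad, solve_mme)


def _oneway_model(y, groups, R=None):
    y = np.asarray(y, float)
    levels = sorted(set(groups))
    Z = np.zeros((y.size, len(levels)))
    for i, g in enumerate(groups):
        Z[i, levels.index(g)] = 1.0
    term = zm.RandomTerm("group", Z, [(g,) for g in levels], "scalar")
    return zm.MixedModel(y, np.ones((y.size, 1)), [term], R=R)


class TestRemlClosedForms:
    def test_balanced_oneway_matches_anova(self):
        # y = (1,3,5,7), two groups of two: REML equals the ANOVA
        # estimators sigma2_e = 2, sigma2_g = 7
        fit = zm.fit_reml(_oneway_model([1, 3, 5, 7], ["a", "a", "b", "b"]))
        comps = fit.term_params()
        assert comps["residual"][0] == pytest.approx(2.0, rel=1e-5)
        assert comps["group"][0] == pytest.approx(7.0, rel=1e-5)
        assert fit.beta[0] == pytest.approx(4.0, rel=1e-8)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_balanced_oneway_random_data(self, seed):
        # general balanced one-way: REML = ANOVA (MSE and (MSB-MSE)/n)
        rng = np.random.default_rng(seed)
        k, n = 6, 4
        y = (rng.normal(0, 3, k).repeat(n) + rng.normal(0, 2, k * n) + 10.0)
        groups = np.arange(k).repeat(n).tolist()
        ybar = y.reshape(k, n).mean(axis=1)
        mse = float(np.sum((y.reshape(k, n) - ybar[:, None]) ** 2) / (k * (n - 1)))
        msb = float(n * np.sum((ybar - ybar.mean()) ** 2) / (k - 1))
        fit = zm.fit_reml(_oneway_model(y, groups))
        comps = fit.term_params()
        assert comps["residual"][0] == pytest.approx(mse, rel=1e-4)
        assert comps["group"][0] == pytest.approx(max((msb - mse) / n, 0.0), rel=1e-4)

    def test_scale_equivariance(self):
        # scaling y by c multiplies the optimal variance components by c^2
        y = [1.0, 3.0, 5.0, 7.0, 2.0, 6.0]
        groups = ["a", "a", "b", "b", "c", "c"]
        c = 7.5
        f1 = zm.fit_reml(_oneway_model(y, groups))
        f2 = zm.fit_reml(_oneway_model([c * v for v in y], groups))
        for name in ("group", "residual"):
            assert f2.term_params()[name][0] == pytest.approx(
                c * c * f1.term_params()[name][0], rel=1e-4)

    def test_zero_G_limit_is_gls_criterion(self):
        # with the random variance at its floor the deviance equals the
        # fixed-effects GLS criterion under covariance R
        y = np.array([1.0, 2.0, 4.0, 8.0])
        R = np.diag([1.0, 2.0, 1.0, 0.5])
        model = _oneway_model(y, ["a", "a", "b", "b"], R=R)
        theta = np.array([-30.0])
        dev = reml_deviance(theta, model)
        # the engine profiles over an orthonormal basis of col(X); use the
        # same basis so the additive constant matches
        X = np.ones((4, 1)) / 2.0
        Ri = np.linalg.inv(R)
        XtRiX = X.T @ Ri @ X
        beta = np.linalg.solve(XtRiX, X.T @ Ri @ y)
        resid = y - X @ beta
        expect = (np.log(np.linalg.det(R)) + np.log(np.linalg.det(XtRiX))
                  + float(resid @ Ri @ resid))
        assert dev == pytest.approx(expect, abs=1e-6)


class TestMME:
    def test_gls_equals_ols_single_mean(self):
        beta, u, C = solve_mme(np.ones((3, 1)), np.zeros((3, 0)),
                               np.zeros((0, 0)), np.eye(3), [1.0, 2.0, 3.0])
        assert beta[0] == pytest.approx(2.0)
        assert C[0, 0] == pytest.approx(1.0 / 3.0)  # sigma2/n with sigma2=1

    def test_oneway_shrinkage_closed_form(self):
        # u_i = n*s2g/(n*s2g + s2e) * (ybar_i - ybar)
        rng = np.random.default_rng(3)
        k, n, s2g, s2e = 4, 5, 6.0, 2.0
        y = rng.normal(20, 3, k * n)
        X = np.ones((k * n, 1))
        Z = np.kron(np.eye(k), np.ones((n, 1)))
        beta, u, _ = solve_mme(X, Z, s2g * np.eye(k), s2e * np.eye(k * n), y)
        ybar_i = y.reshape(k, n).mean(axis=1)
        shrink = n * s2g / (n * s2g + s2e)
        np.testing.assert_allclose(u, shrink * (ybar_i - y.mean()), rtol=1e-8)

    def test_large_G_limit_recovers_fixed_effects(self):
        rng = np.random.default_rng(4)
        k, n = 3, 4
        y = rng.normal(0, 1, k * n) + np.repeat([5.0, -1.0, 2.0], n)
        X = np.ones((k * n, 1))
        Z = np.kron(np.eye(k), np.ones((n, 1)))
        beta, u, _ = solve_mme(X, Z, 1e8 * np.eye(k), np.eye(k * n), y)
        ybar_i = y.reshape(k, n).mean(axis=1)
        np.testing.assert_allclose(beta[0] + u, ybar_i, rtol=1e-5)

    def test_mme_rows_satisfied(self):
        # the V-identity solution satisfies both rows of Henderson's system
        rng = np.random.default_rng(5)
        n, p, q = 12, 2, 4
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Z = rng.integers(0, 2, (n, q)).astype(float)
        A = rng.normal(size=(q, q))
        G = A @ A.T + 0.5 * np.eye(q)
        R = np.diag(rng.uniform(0.5, 2.0, n))
        y = rng.normal(size=n)
        beta, u, _ = solve_mme(X, Z, G, R, y)
        Ri = np.linalg.inv(R)
        r1 = X.T @ Ri @ X @ beta + X.T @ Ri @ Z @ u - X.T @ Ri @ y
        r2 = (Z.T @ Ri @ X @ beta
              + (Z.T @ Ri @ Z + np.linalg.inv(G)) @ u - Z.T @ Ri @ y)
        assert np.max(np.abs(np.concatenate([r1, r2]))) < 1e-8

    def test_matches_raw_mme_inverse_for_pd_G(self):
        rng = np.random.default_rng(6)
        n, q = 10, 3
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Z = rng.integers(0, 2, (n, q)).astype(float)
        G = np.diag(rng.uniform(0.5, 3.0, q))
        R = np.diag(rng.uniform(0.5, 2.0, n))
        y = rng.normal(size=n)
        _, _, C = solve_mme(X, Z, G, R, y)
        Ri = np.linalg.inv(R)
        coef = np.block([
            [X.T @ Ri @ X, X.T @ Ri @ Z],
            [Z.T @ Ri @ X, Z.T @ Ri @ Z + np.linalg.inv(G)]])
        np.testing.assert_allclose(C, np.linalg.inv(coef), atol=1e-8)


class TestFitIdentities:
    """Every fit must satisfy the GLS/EBLUP formulas to 1e-8 relative."""

    def assert_gls_eblup(self, fit):
        model = fit.model
        V = model.build_V(fit.theta)
        if model.estimate_residual:
            V = V  # residual already included by build_V
        Vi = np.linalg.inv(V)
        X, Z = model.X, model.Z
        A = X.T @ Vi @ X
        beta = np.linalg.pinv(A, hermitian=True) @ X.T @ Vi @ model.y
        scale = max(1.0, float(np.max(np.abs(beta))))
        np.testing.assert_allclose(X @ fit.beta, X @ beta,
                                   rtol=1e-8, atol=1e-8 * scale)
        G = model.build_G(fit.theta)
        u = G @ Z.T @ Vi @ (model.y - X @ fit.beta)
        np.testing.assert_allclose(fit.u, u, rtol=1e-8,
                                   atol=1e-8 * max(1.0, float(np.max(np.abs(u)))))

    def test_oneway(self):
        fit = zm.fit_reml(_oneway_model([1, 3, 5, 7, 2, 9],
                                        ["a", "a", "b", "b", "c", "c"]))
        self.assert_gls_eblup(fit)

    def test_stage2_rg1(self, rg1_fit):
        self.assert_gls_eblup(rg1_fit)

    def test_deviance_at_estimate_not_above_truth(self, small_stage2, small_met):
        cfg = small_met["config"]
        model = zm.build_stage2_design(zm.make_model("RG1"), small_stage2,
                                       small_met["covariates"])
        fit = zm.fit_reml(model)
        s2y = model._s2y
        truth_theta = np.log(np.array(
            [cfg.sigma2_location["Middle"], cfg.sigma2_location["North"],
             cfg.sigma2_location["South"], cfg.sigma2_genotype, cfg.sigma2_gz,
             cfg.sigma2_gl["Middle"], cfg.sigma2_gl["North"],
             cfg.sigma2_gl["South"]]) / s2y)
        assert fit.deviance <= reml_deviance(truth_theta, model) + 1e-6


class TestPev:
    def test_fixed_mean_iid(self):
        n, s2 = 8, 3.0
        model = zm.MixedModel(np.arange(n, dtype=float), np.ones((n, 1)), [],
                              R=s2 * np.eye(n))
        fit = zm.fit_reml(model)
        assert zm.pev(fit, K=np.array([1.0])) == pytest.approx(s2 / n, rel=1e-10)

    def test_zero_vectors(self, rg1_fit):
        assert zm.pev(rg1_fit, None, None) == 0.0

    def test_non_estimable_raises(self, rg1_fit):
        K = np.zeros(rg1_fit.p)
        K[rg1_fit.fixed_index(("zone", "North"))] = 1.0
        K[rg1_fit.fixed_index(("intercept",))] = 5.0  # not a cell mean
        with pytest.raises(EstimabilityError):
            zm.pev(rg1_fit, K)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_against_mvn_propagation(self, seed):
        """pev must equal the error variance obtained by propagating the
        joint distribution of (u, e) through the linear estimator --
        an independent path that never touches the C blocks."""
        rng = np.random.default_rng(seed)
        k, n = 3, 4  # 3 groups of 4 -> 12 observations
        N = k * n
        X = np.column_stack([np.ones(N), rng.normal(size=N)])
        Z = np.kron(np.eye(k), np.ones((n, 1)))
        G = np.diag(rng.uniform(1.0, 4.0, k))
        R = np.diag(rng.uniform(0.5, 2.0, N))
        y = rng.normal(size=N)
        beta, u, C = solve_mme(X, Z, G, R, y)
        V = Z @ G @ Z.T + R
        Vi = np.linalg.inv(V)
        A = np.linalg.inv(X.T @ Vi @ X)
        B = A @ X.T @ Vi                      # beta_hat = B y
        P = Vi - Vi @ X @ A @ X.T @ Vi
        H = G @ Z.T @ P                       # u_hat = H y
        K = rng.normal(size=2)
        M = rng.normal(size=k)
        # eta_hat - eta = c' (u, e) with y = X beta + Z u + e
        c_u = Z.T @ (B.T @ K + H.T @ M) - M
        c_e = B.T @ K + H.T @ M
        var = float(c_u @ G @ c_u + c_e @ R @ c_e)
        p = X.shape[1]
        pev_val = float(np.concatenate([K, M]) @ C @ np.concatenate([K, M]))
        assert pev_val == pytest.approx(var, rel=1e-8)

    def test_monotone_in_R(self):
        # inflating R never decreases the pev of a fixed-effect contrast
        rng = np.random.default_rng(9)
        N = 9
        X = np.column_stack([np.ones(N), rng.normal(size=N)])
        Z = np.kron(np.eye(3), np.ones((3, 1)))
        G = 2.0 * np.eye(3)
        R = np.diag(rng.uniform(0.5, 2.0, N))
        y = rng.normal(size=N)
        K = np.array([1.0, 0.3, 0, 0, 0])
        prev = -np.inf
        for c in (1.0, 1.5, 3.0, 10.0):
            _, _, C = solve_mme(X, Z, G, c * R, y)
            val = float(K @ C @ K)
            assert val >= prev - 1e-10
            prev = val


class TestGradient:
    def test_matches_central_differences(self, small_stage2, small_met, clay_spec):
        model = zm.build_stage2_design(zm.make_model("RC2", clay_spec),
                                       small_stage2, small_met["covariates"])
        rng = np.random.default_rng(0)
        th = rng.normal(-1.0, 0.5, model.n_params)
        _, g = reml_deviance_and_grad(th, model)
        for i in rng.choice(th.size, 5, replace=False):
            e = np.zeros_like(th)
            e[i] = 1e-6
            num = (reml_deviance(th + e, model)
                   - reml_deviance(th - e, model)) / 2e-6
            assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-6)

    def test_us3_G_always_psd(self):
        # the log-Cholesky parameterisation cannot produce an indefinite G
        rng = np.random.default_rng(1)
        n = 9
        x = rng.normal(size=n)
        Z = np.zeros((n, 3))
        Z[:, 0], Z[:, 1], Z[:, 2] = 1.0, x, x ** 2
        term = zm.RandomTerm("rc", Z, [("s", r) for r in range(3)], "us3")
        model = zm.MixedModel(rng.normal(size=n), np.ones((n, 1)), [term], R=np.eye(n))
        for _ in range(25):
            th = rng.normal(0, 2, 6)
            G = model.build_G(th)
            assert np.linalg.eigvalsh(G).min() >= -1e-10
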