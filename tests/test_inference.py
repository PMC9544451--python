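"""Active constraints, sandwich covariance, Wald tests and delta-method curves."""

import numpy as np
import pytest
from scipy import stats

from cureph.inference import (baseline_hazard_curve, baseline_survival_curve,
                              find_active_constraints,
                              population_survival_curve,
                              population_survival_gradient,
                              sandwich_covariance, wald_table)
from cureph.likelihood import ModelParameters, incidence_prob
from cureph.optimize import fit
from cureph.simulate import generate_dataset, study2_scenario
from cureph.splines import place_knots


@pytest.fixture(scope="module")
def fitted():
    scn = study2_scenario(n=600, seed=13)
    d = generate_dataset(scn)
    basis = place_knots(d)
    res = fit(d, basis, lam=1.0)
    sandwich_covariance(res)
    return d, basis, res


class TestActiveConstraints:
    def _params(self, theta):
        return ModelParameters(np.zeros(2), np.zeros(1), np.asarray(theta))

    def test_large_theta_never_active(self):
        p = self._params([0.5, 1.0, 2.0])
        assert find_active_constraints(p, np.array([-5.0, -5.0, -5.0])).size == 0

    def test_zero_theta_negative_gradient_active(self):
        p = self._params([0.0, 0.5, 1.0])
        act = find_active_constraints(p, np.array([-0.5, 0.1, 0.0]))
        np.testing.assert_array_equal(act, [0])

    def test_small_theta_positive_gradient_not_active(self):
        p = self._params([1e-4, 0.5, 1.0])
        assert find_active_constraints(p, np.array([0.3, 0.0, 0.0])).size == 0


class TestSandwich:
    def test_reduces_to_inverse_information_at_lambda_zero(self, fitted):
        # at an unpenalized optimum the sandwich collapses to the inverse
        # observed information on the non-active block
        d, basis, _ = fitted
        res0 = fit(d, basis, lam=0.0)
        cov0 = sandwich_covariance(res0)
        H = res0.workspace.hessian(res0.params, 0.0, penalized=False)
        keep = np.setdiff1d(np.arange(H.shape[0]),
                            res0.params.p + res0.params.q + res0.active_set)
        M = -H[np.ix_(keep, keep)]
        assert np.linalg.eigvalsh(M).min() > 0
        np.testing.assert_allclose(cov0[np.ix_(keep, keep)], np.linalg.inv(M),
                                   rtol=1e-6)

    def test_active_rows_exactly_zero_and_reduced_psd(self, fitted):
        _, _, res = fitted
        cov = res.covariance
        k = res.params.p + res.params.q
        if res.active_set.size:
            for u in res.active_set:
                assert np.all(cov[k + u] == 0.0)
                assert np.all(cov[:, k + u] == 0.0)
        keep = np.setdiff1d(np.arange(cov.shape[0]), k + res.active_set)
        eig = np.linalg.eigvalsh(cov[np.ix_(keep, keep)])
        assert eig.min() >= -1e-8 * max(1.0, eig.max())
        assert np.all(np.diag(cov) >= 0.0)


class TestWaldTable:
    def test_unit_normal_row(self, fitted):
        _, _, res = fitted
        import copy
        res2 = copy.copy(res)
        res2.params = ModelParameters(np.array([0.0]), np.zeros(0),
                                      res.params.theta)
        cov = np.zeros((1 + res.params.m, 1 + res.params.m))
        cov[0, 0] = 1.0
        res2.covariance = cov
        tab = wald_table(res2)
        row = tab.iloc[0]
        assert row["ratio"] == pytest.approx(1.0)
        assert row["ci_low"] == pytest.approx(np.exp(-1.959964), rel=1e-4)
        assert row["ci_high"] == pytest.approx(np.exp(1.959964), rel=1e-4)
        assert row["p_value"] == pytest.approx(1.0)

    def test_zero_se_gives_nan_p(self, fitted):
        _, _, res = fitted
        import copy
        res2 = copy.copy(res)
        res2.params = ModelParameters(np.array([0.5]), np.zeros(0),
                                      res.params.theta)
        res2.covariance = np.zeros((1 + res.params.m, 1 + res.params.m))
        tab = wald_table(res2)
        assert np.isnan(tab.iloc[0]["p_value"])

    def test_ci_contains_estimate(self, fitted):
        _, _, res = fitted
        tab = wald_table(res)
        ok = tab["se"] > 0
        assert np.all(tab.loc[ok, "ci_low"] <= tab.loc[ok, "ratio"])
        assert np.all(tab.loc[ok, "ratio"] <= tab.loc[ok, "ci_high"])


class TestCurves:
    def test_baseline_survival_at_origin(self, fitted):
        _, basis, res = fitted
        c = baseline_survival_curve(res, [basis.a])
        assert c["estimate"][0] == 1.0
        assert c["se"][0] == 0.0

    def test_zero_theta_covariance_zero_width(self, fitted):
        _, basis, res = fitted
        import copy
        res2 = copy.copy(res)
        res2.covariance = np.zeros_like(res.covariance)
        c = baseline_survival_curve(res2, [1.0, 1.5])
        np.testing.assert_array_equal(c["se"], 0.0)
        np.testing.assert_allclose(c["lo95"], c["estimate"])

    def test_baseline_survival_monotone_and_bounded(self, fitted):
        _, basis, res = fitted
        t = np.linspace(basis.a, basis.b, 60)
        c = baseline_survival_curve(res, t)
        assert np.all(np.diff(c["estimate"]) <= 1e-12)
        assert np.all((c["lo95"] >= 0) & (c["hi95"] <= 1))
        assert np.all(c["lo95"] <= c["estimate"] + 1e-12)

    def test_hazard_zero_theta(self, fitted):
        _, basis, res = fitted
        import copy
        res2 = copy.copy(res)
        res2.params = ModelParameters(res.params.beta, res.params.gamma,
                                      np.zeros(res.params.m))
        c = baseline_hazard_curve(res2, [0.8, 1.2])
        np.testing.assert_array_equal(c["estimate"], 0.0)

    def test_single_active_basis_variance(self, fitted):
        _, basis, res = fitted
        import copy
        res2 = copy.copy(res)
        cov = np.zeros_like(res.covariance)
        k = res.params.p + res.params.q
        cov[k + 3, k + 3] = 0.04
        res2.covariance = cov
        t = np.array([1.0])
        psi = basis.eval_m(t)[0]
        c = baseline_hazard_curve(res2, t)
        assert c["se"][0] == pytest.approx(psi[3] * 0.2, rel=1e-10)

    def test_population_curve_limits_and_gradient(self, fitted):
        d, basis, res = fitted
        x = np.array([1.0, 0.5])
        z = np.array([1.0, 1.0, 0.5])
        t = np.linspace(basis.a, basis.b, 25)
        c = population_survival_curve(res, x, z, t)
        pi = float(incidence_prob(z, res.params.beta))
        assert np.all(c["estimate"] >= 1.0 - pi - 1e-12)
        assert c["estimate"][0] == pytest.approx(1.0, abs=1e-10)
        # near-certain susceptibility: population curve = conditional curve
        import copy
        res2 = copy.copy(res)
        res2.params = ModelParameters(np.array([30.0, 0.0, 0.0]),
                                      res.params.gamma, res.params.theta)
        Spop, _ = population_survival_gradient(res2, x, z, t)
        from cureph.likelihood import conditional_survival
        S = conditional_survival(t, x, res.params.gamma, res.params.theta,
                                 basis)
        np.testing.assert_allclose(Spop, S, atol=1e-9)

    def test_population_gradient_matches_finite_differences(self, fitted):
        _, basis, res = fitted
        x = np.array([1.0, 0.3])
        z = np.array([1.0, 0.0, 0.7])
        t = np.array([0.9, 1.4])
        _, grad = population_survival_gradient(res, x, z, t)
        v = res.params.pack()
        n_fixed = res.params.p + res.params.q
        import copy
        for j in range(v.size):
            h = 1e-6 * max(1.0, abs(v[j]))
            if j >= n_fixed:
                h = min(h, 0.5 * v[j]) if v[j] > 0 else h
            vp, vm = v.copy(), v.copy()
            vp[j] += h
            if j >= n_fixed and v[j] - h < 0:
                vm[j] = v[j]          # one-sided at the boundary
            else:
                vm[j] -= h
            rp, rm = copy.copy(res), copy.copy(res)
            rp.params = res.params.unpack_like(vp)
            rm.params = res.params.unpack_like(vm)
            Sp, _ = population_survival_gradient(rp, x, z, t)
            Sm, _ = population_survival_gradient(rm, x, z, t)
            num = (Sp - Sm) / (vp[j] - vm[j])
            np.testing.assert_allclose(grad[:, j], num, atol=2e-5)

    def test_loglog_interval_option(self, fitted):
        _, basis, res = fitted
        t = np.linspace(0.8, 1.8, 10)
        c = baseline_survival_curve(res, t, transform="loglog")
        assert np.all((c["lo95"] >= 0) & (c["hi95"] <= 1))
        assert np.all(c["lo95"] <= c["estimate"])
        assert np.all(c["estimate"] <= c["hi95"])
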