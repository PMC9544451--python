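"""Likelihood branches, penalization, and analytic derivatives."""

import numpy as np
import pytest
from scipy.optimize import nnls
from scipy.special import expit

from cureph.data import CensoringType
from cureph.likelihood import (LikelihoodWorkspace, ModelParameters,
                               conditional_survival, incidence_prob,
                               population_survival)
from cureph.splines import SplineBasis, place_knots

from conftest import make_dataset


class TestIncidenceProb:
    def test_zero_linear_predictor_gives_half(self):
        assert incidence_prob(np.zeros(3), np.array([0.0, 1.0, -1.0])) == 0.5

    def test_saturation_without_overflow(self):
        assert incidence_prob(np.array([1.0]), np.array([1000.0])) == 1.0
        assert incidence_prob(np.array([1.0]), np.array([-1000.0])) == 0.0

    def test_scalar_arithmetic(self):
        z = np.array([1.0, 0.0, 0.5])
        beta = np.array([1.0, 0.5, -0.5])
        assert incidence_prob(z, beta) == pytest.approx(expit(0.75))


@pytest.fixture(scope="module")
def weibull_basis_theta():
    """Basis + non-negative coefficients approximating h0(t) = 3 t^2."""
    basis = SplineBasis(order=4, interior_knots=np.linspace(0.1, 1.9, 8),
                        boundary=(1e-6, 2.0))
    grid = np.linspace(basis.a, basis.b, 500)
    theta, _ = nnls(basis.eval_m(grid), 3.0 * grid ** 2)
    return basis, theta


class TestSurvivalFunctions:
    def test_survival_one_at_origin(self, cubic_basis):
        S = conditional_survival([cubic_basis.a], np.array([0.3]),
                                 np.array([0.5]), np.ones(cubic_basis.m),
                                 cubic_basis)
        assert S[0] == 1.0

    def test_zero_hazard_gives_one(self, cubic_basis):
        S = conditional_survival([1.5], np.array([0.3]), np.array([0.5]),
                                 np.zeros(cubic_basis.m), cubic_basis)
        assert S[0] == 1.0

    def test_weibull_closed_form(self, weibull_basis_theta):
        basis, theta = weibull_basis_theta
        S = conditional_survival([1.0], np.zeros(1), np.zeros(1), theta, basis)
        assert S[0] == pytest.approx(np.exp(-1.0), rel=1e-3)

    def test_population_survival_limits(self, weibull_basis_theta):
        basis, theta = weibull_basis_theta
        x = np.zeros(1)
        z = np.array([1.0])
        params = ModelParameters(np.array([30.0]), np.zeros(1), theta)
        t = np.linspace(basis.a, basis.b, 20)
        Spop = population_survival(t, x, z, params, basis)
        S = conditional_survival(t, x, np.zeros(1), theta, basis)
        np.testing.assert_allclose(Spop, S, atol=1e-10)  # pi ~ 1: plain Cox
        # cure plateau: large t with modest pi
        params2 = ModelParameters(np.array([0.4]), np.zeros(1), theta)
        pi = incidence_prob(z, params2.beta)
        Spop_far = population_survival([50.0], x, z, params2, basis)
        assert Spop_far[0] == pytest.approx(1.0 - pi, abs=1e-4)
        assert np.all(Spop >= 1.0 - incidence_prob(z, params.beta) - 1e-12)


def _direct_loglik(d, basis, params):
    """Independent record-by-record oracle for the four likelihood branches."""
    total = 0.0
    for r in d.records:
        pi = float(incidence_prob(r.z, params.beta))
        mu = float(np.exp(r.x @ params.gamma))
        H = lambda t: float(basis.eval_i([t])[0] @ params.theta)
        S = lambda t: np.exp(-H(t) * mu)
        if r.status == CensoringType.EVENT:
            h0 = float(basis.eval_m([r.t_left])[0] @ params.theta)
            total += (np.log(pi) + np.log(h0) + float(r.x @ params.gamma)
                      - H(r.t_left) * mu)
        elif r.status == CensoringType.RIGHT:
            total += np.log(1.0 - pi + pi * S(r.t_left))
        elif r.status == CensoringType.LEFT:
            total += np.log(pi) + np.log(1.0 - S(r.t_right))
        else:
            total += np.log(pi) + np.log(S(r.t_left) - S(r.t_right))
    return total


class TestLogLikelihood:
    def test_right_censored_at_origin_contributes_zero(self, cubic_basis):
        d = make_dataset([cubic_basis.a], [np.inf], [CensoringType.RIGHT])
        ws = LikelihoodWorkspace(d, cubic_basis)
        params = ModelParameters(np.array([0.7, 0.0]), np.array([0.2]),
                                 np.ones(cubic_basis.m))
        assert ws.loglik(params) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_oracle(self, mixed_workspace):
        ws = mixed_workspace
        rng = np.random.default_rng(5)
        params = ModelParameters(rng.normal(0, 0.5, 3), rng.normal(0, 0.3, 2),
                                 rng.uniform(0.05, 1.0, ws.m))
        direct = _direct_loglik(ws.dataset, ws.basis, params)
        assert ws.loglik(params) == pytest.approx(direct, rel=1e-10)

    def test_permutation_invariance(self, mixed_dataset, mixed_workspace):
        from cureph.data import Dataset
        rng = np.random.default_rng(3)
        perm = rng.permutation(mixed_dataset.n)
        d2 = Dataset(mixed_dataset.t_left[perm], mixed_dataset.t_right[perm],
                     mixed_dataset.status[perm], mixed_dataset.X[perm],
                     mixed_dataset.Z[perm])
        ws2 = LikelihoodWorkspace(d2, mixed_workspace.basis)
        params = ModelParameters(np.array([0.3, -0.2, 0.1]),
                                 np.array([0.4, -0.1]),
                                 np.full(mixed_workspace.m, 0.5))
        assert ws2.loglik(params) == pytest.approx(
            mixed_workspace.loglik(params), rel=1e-12)

    def test_penalty_relations(self, mixed_workspace):
        ws = mixed_workspace
        params = ModelParameters(np.zeros(3), np.zeros(2),
                                 np.linspace(0.1, 1.0, ws.m))
        assert ws.penalized_loglik(params, 0.0) == ws.loglik(params)
        assert ws.penalized_loglik(params, 2.0) <= ws.loglik(params)
        z0 = ModelParameters(np.zeros(3), np.zeros(2), np.zeros(ws.m))
        assert ws.penalty(z0) == 0.0


def _fd_gradient(fun, v, h=1e-6):
    g = np.zeros_like(v)
    for j in range(v.size):
        e = np.zeros_like(v)
        e[j] = h * max(1.0, abs(v[j]))
        g[j] = (fun(v + e) - fun(v - e)) / (2 * e[j])
    return g


@pytest.mark.parametrize("with_beta", [True, False])
def test_score_and_hessian_match_finite_differences(mixed_workspace, with_beta):
    ws = mixed_workspace
    rng = np.random.default_rng(17)
    lam = 0.4
    for _ in range(4):
        beta = rng.normal(0, 0.5, 3) if with_beta else None
        params = ModelParameters(beta, rng.normal(0, 0.3, 2),
                                 rng.uniform(0.05, 1.0, ws.m))
        v = params.pack()
        g = ws.score(params, lam)
        H = ws.hessian(params, lam)
        gfd = _fd_gradient(lambda w: ws.penalized_loglik(params.unpack_like(w), lam), v)
        scale = max(1.0, np.max(np.abs(gfd)))
        assert np.max(np.abs(g - gfd)) / scale < 1e-5
        Hfd = np.column_stack([
            (ws.score(params.unpack_like(v + e), lam)
             - ws.score(params.unpack_like(v - e), lam)) / (2 * e[j])
            for j, e in enumerate(
                np.eye(v.size) * (1e-5 * np.maximum(1.0, np.abs(v))))])
        hscale = max(1.0, np.max(np.abs(Hfd)))
        assert np.max(np.abs(H - Hfd)) / hscale < 1e-4
        np.testing.assert_allclose(H, H.T, atol=1e-10)


def test_theta_score_decomposition(mixed_workspace):
    """pos/neg parts are non-negative and reconstruct the unpenalized score."""
    ws = mixed_workspace
    params = ModelParameters(np.array([0.5, 0.2, -0.1]), np.array([0.3, 0.6]),
                             np.linspace(0.2, 1.2, ws.m))
    pos, neg = ws.theta_score_parts(params)
    assert np.all(pos >= 0) and np.all(neg >= 0)
    _, _, g_theta = ws.score_blocks(params, 0.0)
    np.testing.assert_allclose(pos - neg, g_theta, rtol=1e-12)
    # penalty gradient splits as (2 lam R theta)+ - (2 lam R theta)-
    lam = 0.8
    _, _, g_pen = ws.score_blocks(params, lam)
    np.testing.assert_allclose(g_theta - g_pen, 2 * lam * (ws.R @ params.theta),
                               atol=1e-12)
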