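import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from fhdgm.penalty import (
    PenaltySpec,
    adaptive_weights,
    coefficient_path,
    kkt_residual,
    lambda_grid,
    penalized_objective,
    solve_penalized,
)


def generic_convex_solver(beta_mle, H, w, lam, N):
    """Independent oracle: split beta = u - v and solve the smooth bound-
    constrained program with L-BFGS-B."""
    A = -H
    mb = beta_mle.size

    def f(z):
        u, v = z[:mb], z[mb:]
        d = (u - v) - beta_mle
        val = 0.5 * d @ A @ d + N * lam * np.sum(w * (u + v))
        g = A @ d
        return val, np.concatenate([g + N * lam * w, -g + N * lam * w])

    z0 = np.concatenate([np.clip(beta_mle, 0, None), np.clip(-beta_mle, 0, None)])
    res = minimize(
        f, z0, jac=True, method="L-BFGS-B", bounds=[(0, None)] * (2 * mb),
        options={"ftol": 1e-18, "gtol": 1e-14, "maxiter": 5000},
    )
    return res.x[:mb] - res.x[mb:]


def random_instance(rng, mb=None):
    mb = mb or int(rng.integers(2, 13))
    M = rng.standard_normal((mb, mb))
    H = -(M @ M.T + mb * np.eye(mb))
    beta_mle = rng.standard_normal(mb)
    w = 1.0 / np.maximum(np.abs(beta_mle), 1e-2)
    if rng.random() < 0.3:
        w[rng.integers(mb)] = 0.0
    N = int(rng.integers(10, 1000))
    lam = float(rng.uniform(0, 2) / N * mb)
    return beta_mle, H, w, lam, N


class TestAdaptiveWeights:
    def test_gamma_zero_gives_unit_weights(self):
        w = adaptive_weights(np.array([2.0, -3.0, 0.5]), gamma=0.0)
        np.testing.assert_allclose(w, 1.0)

    def test_inverse_magnitude_at_gamma_one(self):
        assert adaptive_weights(np.array([2.0]), 1.0)[0] == pytest.approx(0.5)

    def test_intercept_mask_zeroes_weights(self):
        mask = np.array([True, False])
        w = adaptive_weights(np.array([0.7, 2.0]), 1.0, unpenalized_mask=mask)
        assert w[0] == 0.0 and w[1] == pytest.approx(0.5)

    def test_zero_mle_coefficient_capped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            w = adaptive_weights(np.array([0.0, 1.0]), 1.0)
        assert np.isfinite(w[0]) and w[0] >= 1e10

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            adaptive_weights(np.array([1.0]), -0.5)


class TestLambdaGrid:
    def test_default_grid_structure(self):
        g = lambda_grid()
        assert g.size == 101
        assert g[0] == 0.0
        assert g[1] == pytest.approx(1e-5)
        assert g[-1] == pytest.approx(0.5)
        assert np.all(np.diff(g) > 0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            lambda_grid(0.5, 1e-5)
        with pytest.raises(ValueError):
            lambda_grid(0.0, 0.5)


class TestSolvePenalized:
    def test_lambda_zero_returns_mle(self, rng):
        beta_mle, H, w, _, N = random_instance(rng)
        np.testing.assert_array_equal(solve_penalized(beta_mle, H, w, 0.0, N), beta_mle)

    def test_soft_threshold_closed_form(self):
        N = 100
        H = -N * np.eye(1)
        out = solve_penalized(np.array([1.0]), H, np.array([1.0]), 0.4, N)
        assert out[0] == pytest.approx(0.6, abs=1e-10)

    def test_adaptive_weight_zeroing_condition(self):
        # with w = 1/|b| and H = -N I a coordinate dies iff b^2 <= lambda
        N = 50
        H = -N * np.eye(1)
        out = solve_penalized(np.array([0.5]), H, np.array([2.0]), 0.3, N)
        assert out[0] == 0.0
        out2 = solve_penalized(np.array([0.5]), H, np.array([2.0]), 0.2, N)
        assert out2[0] == pytest.approx(0.1, abs=1e-10)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_diagonal_hessian_matches_soft_threshold_exactly(self, seed):
        rng = np.random.default_rng(seed)
        mb = int(rng.integers(1, 8))
        diag = rng.uniform(0.5, 5.0, mb)
        N = int(rng.integers(5, 500))
        H = -N * np.diag(diag)
        beta_mle = rng.standard_normal(mb)
        w = rng.uniform(0.1, 3.0, mb)
        lam = float(rng.uniform(0, 1))
        out = solve_penalized(beta_mle, H, w, lam, N)
        thresh = lam * w / diag
        expected = np.sign(beta_mle) * np.maximum(np.abs(beta_mle) - thresh, 0.0)
        np.testing.assert_allclose(out, expected, atol=1e-15)

    def test_indefinite_hessian_rejected(self):
        with pytest.raises(ValueError):
            solve_penalized(np.array([1.0, 1.0]), np.eye(2), np.ones(2), 0.1, 10)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            solve_penalized(np.array([1.0]), -np.eye(1), np.ones(1), -0.1, 10)

    def test_matches_generic_solver_and_kkt(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            beta_mle, H, w, lam, N = random_instance(rng)
            b_cd = solve_penalized(beta_mle, H, w, lam, N)
            b_or = generic_convex_solver(beta_mle, H, w, lam, N)
            np.testing.assert_allclose(b_cd, b_or, atol=1e-6)
            assert kkt_residual(b_cd, beta_mle, H, w, lam, N) <= 1e-8 * N

    def test_active_set_backend_agrees_with_coordinate_descent(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            beta_mle, H, w, lam, N = random_instance(rng)
            b_cd = solve_penalized(beta_mle, H, w, lam, N)
            b_as = solve_penalized(beta_mle, H, w, lam, N, backend="active-set")
            np.testing.assert_allclose(b_as, b_cd, atol=1e-7)

    def test_solution_beats_mle_and_origin(self, rng):
        for _ in range(10):
            beta_mle, H, w, lam, N = random_instance(rng)
            b = solve_penalized(beta_mle, H, w, lam, N)
            obj = penalized_objective(b, beta_mle, H, w, lam, N)
            assert obj <= penalized_objective(beta_mle, beta_mle, H, w, lam, N) + 1e-9
            assert obj <= penalized_objective(np.zeros_like(b), beta_mle, H, w, lam, N) + 1e-9


class _QuadraticModel:
    """Minimal stand-in for FittedModel in path tests."""

    def __init__(self, beta_mle, H, n_obs):
        self.beta_mle = beta_mle
        self.hessian_beta = H
        self.n_obs = n_obs
        self.n_curves = n_obs


class TestCoefficientPath:
    def _model(self, rng, mb=10):
        beta_mle, H, w, lam, N = random_instance(rng, mb=mb)
        return _QuadraticModel(beta_mle, H, N)

    def test_path_starts_at_mle(self, rng):
        model = self._model(rng)
        spec = PenaltySpec(lambdas=lambda_grid(1e-4, 0.5, 10))
        path = coefficient_path(model, spec)
        np.testing.assert_array_equal(path.betas[0], model.beta_mle)
        assert path.lambdas[0] == 0.0

    def test_every_path_point_matches_generic_solver(self, rng):
        model = self._model(rng, mb=10)
        w = adaptive_weights(model.beta_mle, 1.0)
        spec = PenaltySpec(lambdas=lambda_grid(1e-4, 0.5, 15))
        path = coefficient_path(model, spec)
        for lam, beta in zip(path.lambdas, path.betas):
            oracle = generic_convex_solver(
                model.beta_mle, model.hessian_beta, w, float(lam), model.n_obs
            )
            np.testing.assert_allclose(beta, oracle, atol=1e-6)

    def test_kkt_residuals_small_along_path(self, rng):
        model = self._model(rng)
        path = coefficient_path(model, PenaltySpec(lambdas=lambda_grid(1e-4, 0.5, 20)))
        assert np.all(path.kkt <= 1e-8 * model.n_obs)

    def test_solution_continuity_under_grid_refinement(self, rng):
        model = self._model(rng)
        coarse = coefficient_path(model, PenaltySpec(lambdas=lambda_grid(1e-3, 0.5, 8)))
        fine = coefficient_path(model, PenaltySpec(lambdas=lambda_grid(1e-3, 0.5, 64)))
        step_coarse = np.abs(np.diff(coarse.betas, axis=0)).max()
        step_fine = np.abs(np.diff(fine.betas, axis=0)).max()
        assert step_fine < step_coarse
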