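import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from fhdgm.basis import make_bspline_basis, make_constant_basis
from fhdgm.model_core import RandomEffectsParams
from fhdgm.state_space import (
    StateSpaceSystem,
    kalman_filter,
    kalman_smoother,
    smoothed_omega,
)


def _system(n=2, K=2, g=(0.7, 0.4), theta=(40.0, 60.0), v=(1.2, 0.5), sig=0.8,
            coords=None, q=2):
    coords = np.array([[9.0, 45.0], [9.5, 45.4], [10.0, 45.0], [9.2, 46.0]])[:n] \
        if coords is None else coords
    psi = RandomEffectsParams(
        g_diag=list(g)[:K], theta=list(theta)[:K], v=list(v)[:K], sigma2_coeffs=[sig]
    )
    h = np.linspace(2.0, 22.0, q)
    b_om = make_bspline_basis((0.0, 24.0), K, max(K - 1, 0)) if K > 1 else make_constant_basis()
    return StateSpaceSystem.build(coords, psi, b_om, make_constant_basis(), h)


def joint_gaussian_loglik(system, resid):
    """Brute-force oracle: assemble the full (T n q) covariance and evaluate."""
    T = resid.shape[0]
    m = system.state_dim
    G = np.diag(system.g_full)
    P0 = system.stationary_cov()
    H = system.emission_matrix()
    nq = H.shape[0]
    covZ = np.zeros((T * m, T * m))
    for t1 in range(T):
        for t2 in range(T):
            C = np.linalg.matrix_power(G, abs(t1 - t2)) @ P0
            covZ[t1 * m : (t1 + 1) * m, t2 * m : (t2 + 1) * m] = C if t1 >= t2 else C.T
    bigH = np.kron(np.eye(T), H)
    Sigma = bigH @ covZ @ bigH.T
    Rdiag = np.tile(np.concatenate([system.sigma2_h] * system.n_stations), T)
    Sigma += np.diag(Rdiag)
    y = resid.reshape(-1)
    return multivariate_normal(mean=np.zeros(T * nq), cov=Sigma).logpdf(y)


class TestFilter:
    def test_degenerate_state_reduces_to_iid_gaussian(self, rng):
        sys_ = _system(v=(0.0, 0.0))
        resid = rng.standard_normal((4, 2, 2))
        fr = kalman_filter(sys_, resid)
        expected = norm(scale=np.sqrt(0.8)).logpdf(resid).sum()
        assert fr.loglik == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("n,T,q,K", [(2, 3, 2, 2), (3, 4, 3, 1), (2, 5, 2, 1)])
    def test_loglik_matches_joint_gaussian_oracle(self, n, T, q, K, rng):
        sys_ = _system(n=n, K=K, q=q)
        resid = rng.standard_normal((T, n, q))
        fr = kalman_filter(sys_, resid)
        ll = joint_gaussian_loglik(sys_, resid)
        assert fr.loglik == pytest.approx(ll, rel=1e-10)

    def test_loglik_with_missing_matches_marginal_oracle(self, rng):
        sys_ = _system(n=2, K=2, q=2)
        resid = rng.standard_normal((3, 2, 2))
        resid[1, 0, 1] = np.nan
        fr = kalman_filter(sys_, resid)
        # oracle: drop the missing coordinate from the joint density
        T, m = 3, sys_.state_dim
        G = np.diag(sys_.g_full)
        P0 = sys_.stationary_cov()
        H = sys_.emission_matrix()
        covZ = np.zeros((T * m, T * m))
        for t1 in range(T):
            for t2 in range(T):
                C = np.linalg.matrix_power(G, abs(t1 - t2)) @ P0
                covZ[t1 * m:(t1 + 1) * m, t2 * m:(t2 + 1) * m] = C if t1 >= t2 else C.T
        bigH = np.kron(np.eye(T), H)
        Sigma = bigH @ covZ @ bigH.T + np.diag(np.tile(np.repeat(0.8, 4), T))
        y = resid.reshape(T, -1).reshape(-1)
        keep = ~np.isnan(y)
        ll = multivariate_normal(cov=Sigma[np.ix_(keep, keep)]).logpdf(y[keep])
        assert fr.loglik == pytest.approx(ll, rel=1e-10)

    def test_masking_leaves_earlier_filter_means_unchanged(self, rng):
        sys_ = _system()
        resid = rng.standard_normal((5, 2, 2))
        fr_full = kalman_filter(sys_, resid)
        resid_masked = resid.copy()
        resid_masked[3, 1, :] = np.nan
        fr_masked = kalman_filter(sys_, resid_masked)
        np.testing.assert_allclose(fr_masked.x_filt[:4], fr_full.x_filt[:4], atol=1e-12)
        assert not np.allclose(fr_masked.x_filt[4], fr_full.x_filt[4])

    def test_loglik_invariant_to_station_ordering(self, rng):
        coords = np.array([[9.0, 45.0], [9.6, 45.5], [10.1, 44.8]])
        psi = RandomEffectsParams(g_diag=[0.6], theta=[50.0], v=[1.0], sigma2_coeffs=[1.0])
        h = np.linspace(1.0, 23.0, 4)
        b = make_constant_basis()
        resid = rng.standard_normal((4, 3, 4))
        sys1 = StateSpaceSystem.build(coords, psi, b, b, h)
        perm = np.array([2, 0, 1])
        sys2 = StateSpaceSystem.build(coords[perm], psi, b, b, h)
        ll1 = kalman_filter(sys1, resid).loglik
        ll2 = kalman_filter(sys2, resid[:, perm, :]).loglik
        assert ll1 == pytest.approx(ll2, rel=1e-12)

    def test_distant_groups_factorise_the_likelihood(self, rng):
        """With a tiny spatial range, two distant clusters are independent and
        the total log-likelihood splits into per-group terms."""
        coords = np.array([[9.0, 45.0], [9.01, 45.01], [14.0, 41.0], [14.01, 41.01]])
        psi = RandomEffectsParams(g_diag=[0.6], theta=[0.5], v=[1.0], sigma2_coeffs=[1.0])
        h = np.linspace(1.0, 23.0, 3)
        b = make_constant_basis()
        resid = rng.standard_normal((4, 4, 3))
        full = kalman_filter(StateSpaceSystem.build(coords, psi, b, b, h), resid).loglik
        g1 = kalman_filter(StateSpaceSystem.build(coords[:2], psi, b, b, h), resid[:, :2]).loglik
        g2 = kalman_filter(StateSpaceSystem.build(coords[2:], psi, b, b, h), resid[:, 2:]).loglik
        assert full == pytest.approx(g1 + g2, rel=1e-8)


class TestSmoother:
    def test_single_day_smoother_equals_filter(self, rng):
        sys_ = _system()
        resid = rng.standard_normal((1, 2, 2))
        sm = kalman_smoother(sys_, resid)
        np.testing.assert_allclose(sm.x_smooth[1], sm.filter_result.x_filt[1], atol=1e-12)
        np.testing.assert_allclose(sm.P_smooth[1], sm.filter_result.P_filt[1], atol=1e-12)

    def test_noiseless_limit_reproduces_residuals(self, rng):
        sys_ = _system(K=2, q=2, sig=1e-10)
        resid = rng.standard_normal((3, 2, 2))
        sm = kalman_smoother(sys_, resid)
        om = smoothed_omega(sys_, sm.x_smooth)
        np.testing.assert_allclose(om, resid, atol=1e-6)

    def test_posterior_moments_match_joint_conditioning_oracle(self, rng):
        sys_ = _system(n=2, K=2, q=2)
        T, m = 3, sys_.state_dim
        resid = rng.standard_normal((T, 2, 2))
        sm = kalman_smoother(sys_, resid)
        G = np.diag(sys_.g_full)
        P0 = sys_.stationary_cov()
        H = sys_.emission_matrix()
        covZ = np.zeros(((T + 1) * m, (T + 1) * m))
        for t1 in range(T + 1):
            for t2 in range(T + 1):
                C = np.linalg.matrix_power(G, abs(t1 - t2)) @ P0
                covZ[t1 * m:(t1 + 1) * m, t2 * m:(t2 + 1) * m] = C if t1 >= t2 else C.T
        bigH = np.kron(np.eye(T), H)
        Sigma = bigH @ covZ[m:, m:] @ bigH.T + 0.8 * np.eye(T * H.shape[0])
        cross = covZ[:, m:] @ bigH.T
        y = resid.reshape(-1)
        mean = (cross @ np.linalg.solve(Sigma, y)).reshape(T + 1, m)
        np.testing.assert_allclose(sm.x_smooth, mean, atol=1e-9)
        post = covZ - cross @ np.linalg.solve(Sigma, cross.T)
        for t in range(T + 1):
            np.testing.assert_allclose(
                sm.P_smooth[t], post[t * m:(t + 1) * m, t * m:(t + 1) * m], atol=1e-9
            )
        for t in range(1, T + 1):
            np.testing.assert_allclose(
                sm.lag_one[t - 1], post[t * m:(t + 1) * m, (t - 1) * m:t * m], atol=1e-9
            )

    def test_smoothing_never_increases_variance(self, rng):
        sys_ = _system(n=3, K=2, q=3)
        resid = rng.standard_normal((6, 3, 3))
        sm = kalman_smoother(sys_, resid)
        fr = sm.filter_result
        for t in range(1, 7):
            gap = fr.P_filt[t] - sm.P_smooth[t]
            assert np.linalg.eigvalsh(0.5 * (gap + gap.T)).min() > -1e-9
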