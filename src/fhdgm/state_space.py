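"""Kalman filter/smoother for the latent diurnal process.

State-space form of the model, conditional on the fixed effects: with the
stacked latent state ``z_t`` (component-major: entry ``i*n + s`` is
component ``i`` at station ``s``),

    r_t = H z_t + eps_t,      eps_t ~ N(0, R)   (R diagonal, sigma^2(h))
    z_t = diag(g) z_{t-1} + eta_t,  eta_t ~ N(0, Q)

where ``r_t`` is the observation vector minus the fixed-effects mean and
``H`` loads each station's state block through the within-day basis.  The
transition is diagonal because the latent components evolve as independent
AR(1) processes; all spatial coupling enters through ``Q``.

The update step runs in information form on the (small) state dimension:
``P_u = (P_p^{-1} + H'R^{-1}H)^{-1}`` with the innovation log-density
obtained from the matrix determinant lemma, so cost per day is cubic in
``n * K_omega`` rather than in the number of observations.  Missing
observations (NaN) are simply dropped from the update.  A covariance-form
fallback handles (semi-)degenerate predicted covariances exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky

from .basis import BasisSystem, eval_basis
from .model_core import (
    RandomEffectsParams,
    build_innovation_covariance,
    error_variance_profile,
)

__all__ = ["StateSpaceSystem", "FilterResult", "SmootherResult", "kalman_filter", "kalman_smoother"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class StateSpaceSystem:
    """Time-invariant system matrices for one station set."""

    n_stations: int
    k_omega: int
    g_full: np.ndarray  # (m,) diagonal transition
    Q: np.ndarray  # (m, m) innovation covariance
    B_omega: np.ndarray  # (q, K) loading basis on the grid
    sigma2_h: np.ndarray  # (q,) observation noise variance

    @property
    def state_dim(self) -> int:
        return self.n_stations * self.k_omega

    @classmethod
    def build(
        cls,
        coords: np.ndarray,
        psi: RandomEffectsParams,
        basis_omega: BasisSystem,
        basis_sigma: BasisSystem,
        h_grid: np.ndarray,
    ) -> "StateSpaceSystem":
        if basis_omega.n_bases != psi.k_omega:
            raise ValueError("loading basis size must equal the number of latent components")
        sig2 = error_variance_profile(psi, basis_sigma, h_grid)
        if np.any(sig2 <= 0):
            raise ValueError("observation noise variance must be positive on the grid")
        n = np.asarray(coords).shape[0]
        return cls(
            n_stations=n,
            k_omega=psi.k_omega,
            g_full=np.repeat(psi.g_diag, n),
            Q=build_innovation_covariance(coords, psi),
            B_omega=eval_basis(basis_omega, h_grid),
            sigma2_h=sig2,
        )

    def stationary_cov(self) -> np.ndarray:
        """Stationary state covariance (Lyapunov solution; diagonal transition)."""
        if not self.Q.any():
            return np.zeros_like(self.Q)
        return self.Q / (1.0 - np.outer(self.g_full, self.g_full))

    def emission_matrix(self, observed: np.ndarray | None = None) -> np.ndarray:
        """Dense H for the (optionally masked) stacked observation vector.

        ``observed`` is an (n, q) boolean mask; rows follow station-major
        order (all grid points of station 0, then station 1, ...).
        """
        n, K, q = self.n_stations, self.k_omega, self.B_omega.shape[0]
        if observed is None:
            observed = np.ones((n, q), dtype=bool)
        rows = []
        for s in range(n):
            hobs = np.flatnonzero(observed[s])
            block = np.zeros((hobs.size, n * K))
            for i in range(K):
                block[:, i * n + s] = self.B_omega[hobs, i]
            rows.append(block)
        return np.vstack(rows) if rows else np.zeros((0, n * K))


@dataclass
class FilterResult:
    x_filt: np.ndarray  # (T+1, m), index 0 = initial state
    P_filt: np.ndarray  # (T+1, m, m)
    x_pred: np.ndarray  # (T+1, m); entry t = prediction of z_t given t-1 (entry 0 unused)
    P_pred: np.ndarray
    loglik: float


@dataclass
class SmootherResult:
    x_smooth: np.ndarray  # (T+1, m)
    P_smooth: np.ndarray  # (T+1, m, m)
    lag_one: np.ndarray  # (T, m, m); entry t-1 = Cov(z_t, z_{t-1} | all data)
    filter_result: FilterResult


def _information_terms(system: StateSpaceSystem, resid_t: np.ndarray, x_pred: np.ndarray):
    """Per-day accumulators A = H'R^-1 H, b = H'R^-1 v plus scalar pieces.

    Exploits the block structure: the state of station s only loads on that
    station's observations, so A is block "diagonal" across stations within
    each component pair.
    """
    n, K = system.n_stations, system.k_omega
    m = n * K
    A = np.zeros((m, m))
    b = np.zeros(m)
    quad = 0.0
    logdet_R = 0.0
    n_obs = 0
    for s in range(n):
        obs = ~np.isnan(resid_t[s])
        if not obs.any():
            continue
        Bs = system.B_omega[obs]  # (qo, K)
        w = 1.0 / system.sigma2_h[obs]
        v = resid_t[s, obs] - Bs @ x_pred[s::n]
        Bw = Bs * w[:, None]
        As = Bs.T @ Bw  # (K, K)
        idx = s + n * np.arange(K)
        A[np.ix_(idx, idx)] += As
        b[idx] += Bw.T @ v
        quad += float(v @ (w * v))
        logdet_R += float(np.sum(np.log(system.sigma2_h[obs])))
        n_obs += int(obs.sum())
    return A, b, quad, logdet_R, n_obs


def kalman_filter(
    system: StateSpaceSystem,
    resid: np.ndarray,
    initial_cov: np.ndarray | None = None,
) -> FilterResult:
    """Forward pass over mean-corrected observations ``resid`` of shape (T, n, q).

    NaN entries are treated as missing and dropped from the corresponding
    update.  The initial state is N(0, stationary covariance) unless an
    explicit ``initial_cov`` is supplied.
    """
    T = resid.shape[0]
    m = system.state_dim
    g = system.g_full
    P0 = system.stationary_cov() if initial_cov is None else initial_cov
    x_filt = np.zeros((T + 1, m))
    P_filt = np.zeros((T + 1, m, m))
    x_pred = np.zeros((T + 1, m))
    P_pred = np.zeros((T + 1, m, m))
    P_filt[0] = P0
    loglik = 0.0
    for t in range(1, T + 1):
        x_p = g * x_filt[t - 1]
        P_p = g[:, None] * P_filt[t - 1] * g[None, :] + system.Q
        P_p = 0.5 * (P_p + P_p.T)
        x_pred[t], P_pred[t] = x_p, P_p

        A, b, quad, logdet_R, n_obs = _information_terms(system, resid[t - 1], x_p)
        if n_obs == 0:
            x_filt[t], P_filt[t] = x_p, P_p
            continue
        if not P_p.any():
            # Degenerate latent process: pure measurement noise.
            x_filt[t], P_filt[t] = x_p, P_p
            loglik += -0.5 * (n_obs * _LOG2PI + logdet_R + quad)
            continue
        try:
            L = cholesky(P_p, lower=True)
            M = L.T @ A @ L
            M[np.diag_indices_from(M)] += 1.0
            cM = cho_factor(M, lower=True)
            logdet_M = 2.0 * float(np.sum(np.log(np.diag(cM[0]))))
            # P_u = L M^{-1} L'
            W = cho_solve(cM, L.T)
            P_u = L @ W
            P_u = 0.5 * (P_u + P_u.T)
            x_u = x_p + P_u @ b
            loglik += -0.5 * (
                n_obs * _LOG2PI + logdet_R + logdet_M + quad - float(b @ P_u @ b)
            )
        except np.linalg.LinAlgError:
            x_u, P_u, ll_t = _covariance_form_update(system, resid[t - 1], x_p, P_p)
            loglik += ll_t
        x_filt[t], P_filt[t] = x_u, P_u
    return FilterResult(x_filt, P_filt, x_pred, P_pred, loglik)


def _covariance_form_update(system, resid_t, x_p, P_p):
    """Joseph-form update in observation space; handles singular P_p exactly."""
    observed = ~np.isnan(resid_t)
    H = system.emission_matrix(observed)
    r_diag = np.concatenate(
        [system.sigma2_h[observed[s]] for s in range(system.n_stations)]
    )
    y = np.concatenate(
        [resid_t[s, observed[s]] for s in range(system.n_stations)]
    )
    v = y - H @ x_p
    S = H @ P_p @ H.T
    S[np.diag_indices_from(S)] += r_diag
    cS = cho_factor(0.5 * (S + S.T), lower=True)
    K = cho_solve(cS, H @ P_p).T
    x_u = x_p + K @ v
    IKH = np.eye(P_p.shape[0]) - K @ H
    P_u = IKH @ P_p @ IKH.T + (K * r_diag[None, :]) @ K.T
    P_u = 0.5 * (P_u + P_u.T)
    logdet_S = 2.0 * float(np.sum(np.log(np.diag(cS[0]))))
    alpha = cho_solve(cS, v)
    ll = -0.5 * (v.size * _LOG2PI + logdet_S + float(v @ alpha))
    return x_u, P_u, ll


def kalman_smoother(
    system: StateSpaceSystem,
    resid: np.ndarray,
    initial_cov: np.ndarray | None = None,
) -> SmootherResult:
    """RTS backward pass; also returns lag-one smoothed cross-covariances."""
    fr = kalman_filter(system, resid, initial_cov=initial_cov)
    T = resid.shape[0]
    m = system.state_dim
    g = system.g_full
    x_s = fr.x_filt.copy()
    P_s = fr.P_filt.copy()
    J = np.zeros((T, m, m))  # J[t] maps smoothing from t+1 back to t
    for t in range(T - 1, -1, -1):
        P_p_next = fr.P_pred[t + 1]
        if not P_p_next.any():
            continue  # J = 0: degenerate prediction, smoothing changes nothing
        PfG = fr.P_filt[t] * g[None, :]  # P_f[t] @ diag(g)
        try:
            cP = cho_factor(P_p_next, lower=True)
            Jt = cho_solve(cP, PfG.T).T
        except np.linalg.LinAlgError:
            Jt = PfG @ np.linalg.pinv(P_p_next, hermitian=True)
        J[t] = Jt
        x_s[t] = fr.x_filt[t] + Jt @ (x_s[t + 1] - fr.x_pred[t + 1])
        P_s[t] = fr.P_filt[t] + Jt @ (P_s[t + 1] - P_p_next) @ Jt.T
        P_s[t] = 0.5 * (P_s[t] + P_s[t].T)
    lag_one = np.empty((T, m, m))
    for t in range(1, T + 1):
        lag_one[t - 1] = P_s[t] @ J[t - 1].T
    return SmootherResult(x_s, P_s, lag_one, fr)


def smoothed_omega(system: StateSpaceSystem, x_smooth: np.ndarray) -> np.ndarray:
    """Map smoothed states to random-effect curves, shape (T, n, q)."""
    T = x_smooth.shape[0] - 1
    n, K = system.n_stations, system.k_omega
    return np.einsum("qk,tkn->tnq", system.B_omega, x_smooth[1:].reshape(T, K, n))
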