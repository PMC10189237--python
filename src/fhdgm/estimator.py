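"""Maximum-likelihood estimation of the full model.

Phase 1 fits {beta, psi} by an expectation–conditional-maximisation (ECM)
scheme: the E-step runs the Kalman smoother on the mean-corrected data;
the M-step updates beta by (weighted) generalised least squares given the
smoothed random effects, the error-variance coefficients by an exact
small-dimensional maximisation, and each latent component's (g, theta, v)
triple by a two-parameter numerical maximisation with the innovation
variance profiled out (the stationary initial-state term is included, so
every conditional update increases the expected complete-data likelihood
and the marginal log-likelihood is non-decreasing across iterations).

Phase 2 computes the Hessian of the marginal log-likelihood in beta at the
MLE with psi fixed.  The marginal model is linear-Gaussian in beta, so
H = -X' Sigma_y^{-1} X exactly; it is accumulated by passing the design
columns through the same innovations decomposition as the data, which
avoids ever forming Sigma_y.

A spatial-partitioning approximation is available: stations are grouped by
k-medoids on geodesic distance and cross-group correlations are dropped,
factorising the likelihood and the E-step over groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.optimize import minimize

from .basis import BasisSystem, eval_basis, make_bspline_basis, make_constant_basis, make_fourier_basis
from .model_core import (
    FHDGMParams,
    FunctionalDataset,
    RandomEffectsParams,
    build_design,
    distance_matrix_km,
)
from .state_space import StateSpaceSystem, kalman_smoother, smoothed_omega

__all__ = ["EMConfig", "FittedModel", "fit_mle", "hessian_beta", "spatial_partition"]


@dataclass
class EMConfig:
    """Estimation settings.

    ``tol`` is the relative log-likelihood change below which the ECM loop
    stops; ``n_partitions`` > 1 activates the spatial-partitioning
    likelihood approximation; ``fit_random_effects=False`` drops the latent
    process entirely (iterated weighted least squares on the fixed effects).
    """

    basis_mu: BasisSystem = field(default_factory=lambda: make_bspline_basis((0.0, 24.0), 7, 3))
    basis_omega: BasisSystem = field(default_factory=lambda: make_fourier_basis(24.0, 3))
    basis_sigma: BasisSystem = field(default_factory=make_constant_basis)
    tol: float = 1e-4
    max_iter: int = 400
    n_partitions: int = 1
    fit_random_effects: bool = True
    v_floor: float = 1e-10
    theta_init: float | None = None
    g_init: float = 0.5


@dataclass
class FittedModel:
    """MLE result: parameters, log-likelihood, Hessian in beta, diagnostics."""

    beta_mle: np.ndarray
    psi_mle: RandomEffectsParams
    loglik: float
    hessian_beta: np.ndarray | None
    config: EMConfig
    n_curves: int  # N = n * T
    n_obs: int  # observed scalar data points (<= N * q); penalty scale
    n_iter: int
    converged: bool
    final_rel_change: float
    loglik_path: np.ndarray
    partition_labels: np.ndarray | None = None

    @property
    def params(self) -> FHDGMParams:
        return FHDGMParams(beta=self.beta_mle, psi=self.psi_mle)


# ---------------------------------------------------------------------------
# spatial partitioning


def spatial_partition(coords: np.ndarray, k: int) -> np.ndarray:
    """Group stations into ``k`` spatially coherent clusters (k-medoids/PAM).

    Deterministic: medoids are seeded by the most central station followed
    by farthest-point additions, then refined by alternating assignment and
    medoid updates on the geodesic distance matrix.
    """
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be between 1 and n={n}")
    if k == 1:
        return np.zeros(n, dtype=int)
    if k == n:
        return np.arange(n)
    d = distance_matrix_km(coords)
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        mind = d[:, medoids].min(axis=1)
        medoids.append(int(np.argmax(mind)))
    medoids_arr = np.array(medoids)
    for _ in range(100):
        labels = np.argmin(d[:, medoids_arr], axis=1)
        new_medoids = medoids_arr.copy()
        for j in range(k):
            members = np.flatnonzero(labels == j)
            if members.size:
                within = d[np.ix_(members, members)].sum(axis=1)
                new_medoids[j] = members[np.argmin(within)]
        if np.array_equal(new_medoids, medoids_arr):
            break
        medoids_arr = new_medoids
    return np.argmin(d[:, medoids_arr], axis=1)


# ---------------------------------------------------------------------------
# ECM machinery


def _partition_groups(labels: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(labels == g) for g in np.unique(labels)]


def _per_station_smoothed_cov(P_smooth: np.ndarray, n: int, K: int) -> np.ndarray:
    """Extract per-station K x K smoothed state covariances, shape (T, n, K, K)."""
    T = P_smooth.shape[0] - 1
    P5 = P_smooth[1:].reshape(T, K, n, K, n)
    return np.einsum("tksls->tskl", P5)


def _component_block(mat: np.ndarray, i: int, n: int) -> np.ndarray:
    return mat[i * n : (i + 1) * n, i * n : (i + 1) * n]


class _LatentMStep:
    """Per-component (g, theta, v) conditional maximisation across groups."""

    def __init__(self, group_dists, group_stats, T: int):
        self.group_dists = group_dists  # list of (n_g, n_g) distance matrices
        self.group_stats = group_stats  # list of dicts with S11, S10, S00, E0 per component
        self.T = T

    def negloglik(self, i: int, a: float, u: float) -> tuple[float, float]:
        """Profiled negative expected complete-data loglik for component i.

        Returns (value, profiled v).
        """
        g = np.tanh(a)
        theta = np.exp(u)
        T = self.T
        total_n = 0
        logdet_sum = 0.0
        tr_m = 0.0
        tr_0 = 0.0
        for d, stats in zip(self.group_dists, self.group_stats):
            rho = np.exp(-d / theta)
            c = cho_factor(rho + 1e-10 * np.eye(d.shape[0]), lower=True)
            logdet_sum += 2.0 * float(np.sum(np.log(np.diag(c[0]))))
            S11, S10, S00, E0 = (stats[key][i] for key in ("S11", "S10", "S00", "E0"))
            M = S11 - g * (S10 + S10.T) + g * g * S00
            tr_m += float(np.trace(cho_solve(c, M)))
            tr_0 += float(np.trace(cho_solve(c, E0)))
            total_n += d.shape[0]
        v = (tr_m + (1.0 - g * g) * tr_0) / (total_n * (T + 1))
        v = max(v, 1e-12)
        value = 0.5 * (
            (T + 1) * (total_n * (np.log(v) + 1.0) + logdet_sum)
            - total_n * np.log1p(-g * g)
        )
        return value, v

    def optimise(self, i: int, g0: float, theta0: float) -> tuple[float, float, float]:
        x0 = np.array([np.arctanh(np.clip(g0, -0.999, 0.999)), np.log(theta0)])
        res = minimize(
            lambda x: self.negloglik(i, x[0], x[1])[0],
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 400},
        )
        a, u = res.x
        _, v = self.negloglik(i, a, u)
        return float(np.tanh(a)), float(np.exp(u)), float(v)


def _update_sigma2(
    basis_sigma: BasisSystem,
    h_grid: np.ndarray,
    m_h: np.ndarray,
    c_h: np.ndarray,
    current: np.ndarray,
) -> np.ndarray:
    """Exact conditional maximisation of the error-variance coefficients."""
    B = eval_basis(basis_sigma, h_grid)
    if basis_sigma.n_bases == 1:
        col = B[:, 0]
        coef = float(np.sum(c_h * m_h / col) / np.sum(c_h))
        return np.array([coef])

    def obj(co):
        s2 = B @ co
        val = float(np.sum(c_h * (np.log(s2) + m_h / s2)))
        grad = B.T @ (c_h * (1.0 / s2 - m_h / s2**2))
        return val, grad

    res = minimize(
        obj, np.maximum(current, 1e-6), jac=True, method="L-BFGS-B",
        bounds=[(1e-8, None)] * basis_sigma.n_bases,
    )
    return np.maximum(res.x, 1e-10)


def fit_mle(data: FunctionalDataset, config: EMConfig | None = None) -> FittedModel:
    """Maximum-likelihood fit of {beta, psi} (Phase 1) plus the beta Hessian (Phase 2)."""
    config = config or EMConfig()
    T, n, q = data.y.shape
    h = data.h_grid
    X = build_design(data, config.basis_mu)  # (T*n*q, mb)
    y_flat = data.y.reshape(-1)
    obs_mask = ~np.isnan(y_flat)
    Xo = X[obs_mask]
    yo = y_flat[obs_mask]
    h_of_row = np.tile(h, T * n)[obs_mask]
    h_pos = np.tile(np.arange(q), T * n)[obs_mask]

    K_sig = config.basis_sigma.n_bases
    B_sig = eval_basis(config.basis_sigma, h)

    # counts per grid point (for the sigma^2 update)
    c_h = np.bincount(h_pos, minlength=q).astype(float)

    # --- initialisation -----------------------------------------------------
    XtX = Xo.T @ Xo
    cXtX = cho_factor(XtX, lower=True)
    beta = cho_solve(cXtX, Xo.T @ yo)
    resid0 = yo - Xo @ beta
    var0 = float(np.var(resid0))

    if not config.fit_random_effects:
        return _fit_no_latent(
            data, config, Xo, yo, h_pos, c_h, B_sig, cXtX, beta, var0
        )

    K = config.basis_omega.n_bases
    dists_all = distance_matrix_km(data.coords)
    if config.theta_init is not None:
        theta0 = config.theta_init
    else:
        off = dists_all[np.triu_indices(n, 1)]
        theta0 = float(np.median(off)) if off.size and off.max() > 0 else 50.0
    g0 = config.g_init
    psi = RandomEffectsParams(
        g_diag=np.full(K, g0),
        theta=np.full(K, max(theta0, 1e-3)),
        v=np.full(K, max(var0 / (2 * K) * (1 - g0**2), 1e-4)),
        sigma2_coeffs=_init_sigma2_coeffs(K_sig, var0 / 2),
    )

    labels = spatial_partition(data.coords, config.n_partitions)
    groups = _partition_groups(labels)
    group_dists = [dists_all[np.ix_(g, g)] for g in groups]

    sig2_const = K_sig == 1  # weights cancel in the beta update
    loglik_path: list[float] = []
    rel_change = np.inf
    converged = False
    n_iter = 0

    for it in range(1, config.max_iter + 1):
        n_iter = it
        # --- E-step per group
        resid = (y_flat - X @ beta).reshape(T, n, q)
        loglik = 0.0
        omega_hat = np.zeros((T, n, q))
        var_omega = np.zeros((T, n, q))
        group_stats = []
        for g_idx, gd in zip(groups, group_dists):
            sub_coords = data.coords[g_idx]
            system = StateSpaceSystem.build(
                sub_coords, psi, config.basis_omega, config.basis_sigma, h
            )
            sm = kalman_smoother(system, resid[:, g_idx, :])
            loglik += sm.filter_result.loglik
            omega_hat[:, g_idx, :] = smoothed_omega(system, sm.x_smooth)
            Ps_st = _per_station_smoothed_cov(sm.P_smooth, len(g_idx), K)
            var_omega[:, g_idx, :] = np.einsum(
                "hk,tskl,hl->tsh", system.B_omega, Ps_st, system.B_omega
            )
            ng = len(g_idx)
            S11 = np.einsum("tij->ij", sm.P_smooth[1:]) + sm.x_smooth[1:].T @ sm.x_smooth[1:]
            S00 = np.einsum("tij->ij", sm.P_smooth[:-1]) + sm.x_smooth[:-1].T @ sm.x_smooth[:-1]
            S10 = np.einsum("tij->ij", sm.lag_one) + sm.x_smooth[1:].T @ sm.x_smooth[:-1]
            E0 = sm.P_smooth[0] + np.outer(sm.x_smooth[0], sm.x_smooth[0])
            group_stats.append(
                {
                    "S11": [_component_block(S11, i, ng) for i in range(K)],
                    "S10": [_component_block(S10, i, ng) for i in range(K)],
                    "S00": [_component_block(S00, i, ng) for i in range(K)],
                    "E0": [_component_block(E0, i, ng) for i in range(K)],
                }
            )
        loglik_path.append(loglik)
        if it > 1:
            rel_change = abs(loglik_path[-1] - loglik_path[-2]) / (1.0 + abs(loglik_path[-1]))
            if rel_change < config.tol:
                converged = True
                break

        # --- M-step: beta (GLS given smoothed omega)
        target = y_flat - omega_hat.reshape(-1)
        if sig2_const:
            beta = cho_solve(cXtX, Xo.T @ target[obs_mask])
        else:
            sig2_row = (B_sig @ psi.sigma2_coeffs)[h_pos]
            w = 1.0 / sig2_row
            beta = np.linalg.solve(Xo.T @ (Xo * w[:, None]), Xo.T @ (w * target[obs_mask]))

        # --- M-step: sigma^2 coefficients
        res_om = (y_flat - X @ beta).reshape(T, n, q) - omega_hat
        sq = res_om**2 + var_omega
        sq_flat = sq.reshape(-1)[obs_mask]
        m_h = np.bincount(h_pos, weights=sq_flat, minlength=q) / np.maximum(c_h, 1)
        sigma2_coeffs = _update_sigma2(
            config.basis_sigma, h, m_h, c_h, psi.sigma2_coeffs
        )

        # --- M-step: latent (g, theta, v) per component
        mstep = _LatentMStep(group_dists, group_stats, T)
        g_new = np.empty(K)
        th_new = np.empty(K)
        v_new = np.empty(K)
        for i in range(K):
            g_new[i], th_new[i], v_new[i] = mstep.optimise(i, psi.g_diag[i], psi.theta[i])
        psi = RandomEffectsParams(
            g_diag=np.clip(g_new, -0.999999, 0.999999),
            theta=np.maximum(th_new, 1e-6),
            v=np.maximum(v_new, config.v_floor),
            sigma2_coeffs=sigma2_coeffs,
        )

    if not converged:
        warnings.warn(
            f"EM did not converge in {config.max_iter} iterations "
            f"(last relative change {rel_change:.2e}); returning best iterate",
            RuntimeWarning,
        )

    # Phase 2: exact GLS polish of beta and Hessian at psi-hat.
    beta_gls, H_beta, loglik_final = _gls_and_hessian(data, config, psi, labels)
    return FittedModel(
        beta_mle=beta_gls,
        psi_mle=psi,
        loglik=loglik_final,
        hessian_beta=H_beta,
        config=config,
        n_curves=data.n_curves,
        n_obs=int(obs_mask.sum()),
        n_iter=n_iter,
        converged=converged,
        final_rel_change=float(rel_change),
        loglik_path=np.asarray(loglik_path),
        partition_labels=labels,
    )


def _init_sigma2_coeffs(k_sig: int, value: float) -> np.ndarray:
    return np.full(k_sig, max(value, 1e-4))


def _fit_no_latent(data, config, Xo, yo, h_pos, c_h, B_sig, cXtX, beta, var0):
    """Fixed-effects-only fit: iterate WLS for beta and the variance profile."""
    T, n, q = data.y.shape
    K = config.basis_omega.n_bases
    sigma2_coeffs = _init_sigma2_coeffs(config.basis_sigma.n_bases, var0)
    loglik_path = []
    prev = -np.inf
    rel_change = np.inf
    converged = False
    n_iter = 0
    for it in range(1, config.max_iter + 1):
        n_iter = it
        sig2_row = (B_sig @ sigma2_coeffs)[h_pos]
        w = 1.0 / sig2_row
        if config.basis_sigma.n_bases == 1:
            beta = cho_solve(cXtX, Xo.T @ yo)
        else:
            beta = np.linalg.solve(Xo.T @ (Xo * w[:, None]), Xo.T @ (w * yo))
        r = yo - Xo @ beta
        loglik = -0.5 * float(
            r.size * np.log(2 * np.pi) + np.sum(np.log(sig2_row)) + r @ (w * r)
        )
        loglik_path.append(loglik)
        rel_change = abs(loglik - prev) / (1.0 + abs(loglik))
        if it > 1 and rel_change < config.tol:
            converged = True
            break
        prev = loglik
        m_h = np.bincount(h_pos, weights=r**2, minlength=q) / np.maximum(c_h, 1)
        sigma2_coeffs = _update_sigma2(config.basis_sigma, data.h_grid, m_h, c_h, sigma2_coeffs)
    psi = RandomEffectsParams(
        g_diag=np.zeros(K), theta=np.full(K, 50.0), v=np.zeros(K),
        sigma2_coeffs=sigma2_coeffs,
    )
    sig2_row = (B_sig @ sigma2_coeffs)[h_pos]
    H_beta = -(Xo.T @ (Xo / sig2_row[:, None]))
    return FittedModel(
        beta_mle=beta,
        psi_mle=psi,
        loglik=loglik_path[-1],
        hessian_beta=H_beta,
        config=config,
        n_curves=data.n_curves,
        n_obs=yo.size,
        n_iter=n_iter,
        converged=converged,
        final_rel_change=float(rel_change),
        loglik_path=np.asarray(loglik_path),
        partition_labels=np.zeros(n, dtype=int),
    )


# ---------------------------------------------------------------------------
# Phase 2: GLS / Hessian through the innovations decomposition


def _gls_and_hessian(
    data: FunctionalDataset,
    config: EMConfig,
    psi: RandomEffectsParams,
    labels: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Exact marginal GLS for beta and H = -X' Sigma_y^{-1} X given psi.

    The design columns are filtered jointly with the data: the Kalman
    recursions are linear, so the innovations of ``[X, y]`` give
    ``F = [X y]' Sigma_y^{-1} [X y]`` by accumulating per-day quadratic
    forms.  Works block-wise under spatial partitioning.
    """
    T, n, q = data.y.shape
    h = data.h_grid
    X = build_design(data, config.basis_mu)
    mb = X.shape[1]
    c = mb + 1
    groups = _partition_groups(labels)
    F = np.zeros((c, c))
    logdet = 0.0
    n_obs_total = 0
    for g_idx in groups:
        system = StateSpaceSystem.build(
            data.coords[g_idx], psi, config.basis_omega, config.basis_sigma, h
        )
        ng = len(g_idx)
        m = system.state_dim
        # observation matrix per day for this group: (n_g*q, c) in station-major order
        Xg = X.reshape(T, n, q, mb)[:, g_idx]
        Yg = data.y[:, g_idx]
        Z = np.concatenate([Xg, Yg[..., None]], axis=3)  # (T, ng, q, c)
        mask = ~np.isnan(Yg)  # (T, ng, q)

        g_diag = system.g_full
        P = system.stationary_cov()
        Xi = np.zeros((m, c))
        B_om = system.B_omega
        sig2 = system.sigma2_h
        for t in range(T):
            Xi = g_diag[:, None] * Xi
            P = g_diag[:, None] * P * g_diag[None, :] + system.Q
            P = 0.5 * (P + P.T)
            A = np.zeros((m, m))
            b = np.zeros((m, c))
            quad = np.zeros((c, c))
            logdet_R = 0.0
            n_obs = 0
            for s in range(ng):
                obs = mask[t, s]
                if not obs.any():
                    continue
                Bs = B_om[obs]
                w = 1.0 / sig2[obs]
                idx = s + ng * np.arange(system.k_omega)
                V = Z[t, s, obs] - Bs @ Xi[idx]  # (qo, c)
                Bw = Bs * w[:, None]
                A[np.ix_(idx, idx)] += Bs.T @ Bw
                b[idx] += Bw.T @ V
                quad += V.T @ (V * w[:, None])
                logdet_R += float(np.sum(np.log(sig2[obs])))
                n_obs += int(obs.sum())
            if n_obs == 0:
                continue
            if not P.any():
                F += quad
                logdet += logdet_R
                n_obs_total += n_obs
                continue
            try:
                L = cholesky(P, lower=True)
                M = L.T @ A @ L
                M[np.diag_indices_from(M)] += 1.0
                cM = cho_factor(M, lower=True)
                logdet_M = 2.0 * float(np.sum(np.log(np.diag(cM[0]))))
                P_u = L @ cho_solve(cM, L.T)
                P_u = 0.5 * (P_u + P_u.T)
            except np.linalg.LinAlgError:
                P_reg = P + 1e-10 * max(float(np.trace(P)) / m, 1e-30) * np.eye(m)
                L = cholesky(P_reg, lower=True)
                M = L.T @ A @ L
                M[np.diag_indices_from(M)] += 1.0
                cM = cho_factor(M, lower=True)
                logdet_M = 2.0 * float(np.sum(np.log(np.diag(cM[0]))))
                P_u = L @ cho_solve(cM, L.T)
                P_u = 0.5 * (P_u + P_u.T)
            F += quad - b.T @ P_u @ b
            logdet += logdet_R + logdet_M
            n_obs_total += n_obs
            Xi = Xi + P_u @ b
            P = P_u
    Fxx = F[:mb, :mb]
    Fxy = F[:mb, mb]
    Fyy = F[mb, mb]
    beta = np.linalg.solve(0.5 * (Fxx + Fxx.T), Fxy)
    loglik = -0.5 * (n_obs_total * np.log(2 * np.pi) + logdet + Fyy - float(Fxy @ beta))
    H = -0.5 * (Fxx + Fxx.T)
    return beta, H, loglik


def hessian_beta(model: FittedModel, data: FunctionalDataset) -> np.ndarray:
    """Hessian of the marginal log-likelihood in beta at the MLE (psi fixed)."""
    labels = (
        model.partition_labels
        if model.partition_labels is not None
        else np.zeros(data.n_stations, dtype=int)
    )
    _, H, _ = _gls_and_hessian(data, model.config, model.psi_mle, labels)
    eig = np.linalg.eigvalsh(0.5 * (H + H.T))
    if eig.max() >= 0:
        raise ValueError(
            "Hessian in beta is not negative definite; the MLE appears invalid "
            f"(max eigenvalue {eig.max():.3e})"
        )
    return H
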