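"""Model parameterisation and deterministic building blocks.

The functional hidden dynamic geostatistical model decomposes an observed
curve at station ``s`` and day ``t`` into

    y_{s,t}(h) = mu_{s,t}(h) + omega_{s,t}(h) + eps_{s,t}(h)

where ``mu`` is a functional linear predictor (intercept curve plus
covariate-effect curves, all spanned by a common basis), ``omega`` loads a
station-level latent Markov state onto a second basis, and ``eps`` is white
noise whose variance may itself vary over the within-day domain.

This module holds the parameter containers, the exponential spatial
correlation, the stacked innovation covariance of the latent process, the
error-variance profile and the expanded regression design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BasisSystem, eval_basis

__all__ = [
    "RandomEffectsParams",
    "FHDGMParams",
    "FunctionalDataset",
    "exp_correlation",
    "haversine_km",
    "distance_matrix_km",
    "build_innovation_covariance",
    "error_variance_profile",
    "build_design",
]

_EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class RandomEffectsParams:
    """Parameters of the latent process and measurement error.

    ``g_diag`` are the diagonal AR(1) transition coefficients of the
    K_omega latent components (|g| < 1 for stationarity); ``theta`` the
    exponential spatial ranges in km; ``v`` the innovation variances; and
    ``sigma2_coeffs`` the non-negative coefficients of the error-variance
    profile on its own basis.
    """

    g_diag: np.ndarray
    theta: np.ndarray
    v: np.ndarray
    sigma2_coeffs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "g_diag", np.atleast_1d(np.asarray(self.g_diag, float)))
        object.__setattr__(self, "theta", np.atleast_1d(np.asarray(self.theta, float)))
        object.__setattr__(self, "v", np.atleast_1d(np.asarray(self.v, float)))
        object.__setattr__(
            self, "sigma2_coeffs", np.atleast_1d(np.asarray(self.sigma2_coeffs, float))
        )
        k = self.g_diag.size
        if self.theta.size != k or self.v.size != k:
            raise ValueError("g_diag, theta and v must have one entry per latent component")
        if np.any(np.abs(self.g_diag) >= 1.0):
            raise ValueError("transition coefficients must satisfy |g| < 1")
        if np.any(self.theta <= 0):
            raise ValueError("spatial ranges must be positive")
        if np.any(self.v < 0):
            raise ValueError("innovation variances must be non-negative")
        if np.any(self.sigma2_coeffs < 0):
            raise ValueError("error-variance coefficients must be non-negative")

    @property
    def k_omega(self) -> int:
        return self.g_diag.size


@dataclass(frozen=True)
class FHDGMParams:
    """Full parameter set: stacked fixed-effect coefficients plus random-effect set."""

    beta: np.ndarray
    psi: RandomEffectsParams

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.asarray(self.beta, float).ravel())

    def beta_blocks(self, k_mu: int) -> np.ndarray:
        """Reshape the stacked vector into one row per regressor (intercept first)."""
        if self.beta.size % k_mu:
            raise ValueError("stacked beta length is not a multiple of K_mu")
        return self.beta.reshape(-1, k_mu)


@dataclass
class FunctionalDataset:
    """Functional observations on a common within-day grid.

    Arrays are stored day-major: ``y`` has shape ``(T, n, q)`` (NaN marks a
    missing response) and ``x`` has shape ``(T, n, q, p)``.  ``N = n * T``
    functional curves in total.
    """

    station_ids: list[str]
    coords: np.ndarray  # (n, 2) lon, lat in decimal degrees
    t_index: np.ndarray  # (T,)
    h_grid: np.ndarray  # (q,)
    y: np.ndarray  # (T, n, q)
    x: np.ndarray  # (T, n, q, p)
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        self.t_index = np.asarray(self.t_index)
        self.h_grid = np.asarray(self.h_grid, float)
        self.y = np.asarray(self.y, float)
        self.x = np.asarray(self.x, float)
        n, T, q = self.n_stations, self.n_days, self.n_points
        if self.coords.shape != (n, 2):
            raise ValueError("coords must be (n_stations, 2)")
        if self.y.shape != (T, n, q):
            raise ValueError(f"y must have shape {(T, n, q)}, got {self.y.shape}")
        if self.x.ndim != 4 or self.x.shape[:3] != (T, n, q):
            raise ValueError("x must have shape (T, n, q, p)")

    @property
    def n_stations(self) -> int:
        return len(self.station_ids)

    @property
    def n_days(self) -> int:
        return self.t_index.size

    @property
    def n_points(self) -> int:
        return self.h_grid.size

    @property
    def n_covariates(self) -> int:
        return self.x.shape[3]

    @property
    def n_curves(self) -> int:
        return self.n_stations * self.n_days

    def copy(self) -> "FunctionalDataset":
        return FunctionalDataset(
            station_ids=list(self.station_ids),
            coords=self.coords.copy(),
            t_index=self.t_index.copy(),
            h_grid=self.h_grid.copy(),
            y=self.y.copy(),
            x=self.x.copy(),
            name=self.name,
        )


def exp_correlation(d, theta: float):
    """Exponential correlation ``exp(-d / theta)`` at distance ``d`` (km)."""
    if theta <= 0:
        raise ValueError("spatial range theta must be positive")
    d = np.asarray(d, float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    out = np.exp(-d / theta)
    return float(out) if out.ndim == 0 else out


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points in decimal degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def distance_matrix_km(coords: np.ndarray) -> np.ndarray:
    """Pairwise geodesic distances (km) for an ``(n, 2)`` lon/lat array."""
    coords = np.asarray(coords, float)
    lon = coords[:, 0][:, None]
    lat = coords[:, 1][:, None]
    return haversine_km(lon, lat, lon.T, lat.T)


def build_innovation_covariance(
    coords: np.ndarray, params: RandomEffectsParams
) -> np.ndarray:
    """Stacked innovation covariance of the latent process.

    Component-major block-diagonal: block ``i`` is ``v_i * exp(-d/theta_i)``
    over the ``n`` stations, so the full matrix is ``(n*K_omega)`` square.
    Zero-variance components contribute a zero block (degenerate but valid).
    """
    d = distance_matrix_km(coords)
    n = d.shape[0]
    k = params.k_omega
    out = np.zeros((n * k, n * k))
    for i in range(k):
        block = params.v[i] * exp_correlation(d, params.theta[i])
        out[i * n : (i + 1) * n, i * n : (i + 1) * n] = block
    return out


def error_variance_profile(
    params: RandomEffectsParams, basis_sigma: BasisSystem, h_grid: np.ndarray
) -> np.ndarray:
    """sigma^2(h) on a grid; non-negative by construction for B-spline bases."""
    if params.sigma2_coeffs.size != basis_sigma.n_bases:
        raise ValueError("sigma2 coefficient length must match the variance basis")
    return eval_basis(basis_sigma, h_grid) @ params.sigma2_coeffs


def build_design(dataset: FunctionalDataset, basis_mu: BasisSystem) -> np.ndarray:
    """Expanded fixed-effects design matrix.

    One row per (t, s, h) cell in day-major order; the column for regressor
    ``j`` and basis ``k`` holds ``X_j(h) * B_k(h)``, with the intercept
    (X_0 = 1) block first.  Shape ``(T*n*q, (p+1)*K_mu)``.
    """
    T, n, q, p = (*dataset.y.shape, dataset.n_covariates)
    if np.isnan(dataset.x).any():
        missing_x = np.isnan(dataset.x).any(axis=3)
        if np.any(missing_x & ~np.isnan(dataset.y)):
            raise ValueError("missing covariate value for an observed response")
    B = eval_basis(basis_mu, dataset.h_grid)  # (q, K)
    K = basis_mu.n_bases
    X_aug = np.concatenate(
        [np.ones((T, n, q, 1)), dataset.x], axis=3
    )  # (T, n, q, p+1)
    # outer product over the last axes -> (T, n, q, p+1, K)
    design = X_aug[..., :, None] * B[None, None, :, None, :]
    return design.reshape(T * n * q, (p + 1) * K)
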