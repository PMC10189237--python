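"""K-fold cross-validation over functional curves and penalty selection.

The cross-validation unit is the whole functional observation (one station
-day curve), so N = n*T curves are randomly partitioned into K folds.  For
a held-out curve the prediction is

    yhat_{s,t}(h, lambda) = x_{s,t}(h)' beta(lambda) + omega_hat_{s,t}(h)

where the random effect is obtained by running the Kalman smoother on the
training data with the held-out curves masked as missing — spatial and
temporal correlation then interpolates the latent state at the held-out
(station, day) pairs.

Prediction-error metrics per fold: MSE = mean squared error over the
fold's curves and grid points, RMSE = sqrt(MSE), MAE = mean absolute
error.  Two selection rules are provided: the grid argmin of the mean PE
and the one-standard-error rule (the largest lambda whose mean PE is
within one standard error of the minimum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .estimator import EMConfig, FittedModel, fit_mle, _partition_groups
from .model_core import FunctionalDataset, build_design
from .penalty import PenaltyPath, PenaltySpec, coefficient_path
from .state_space import StateSpaceSystem, kalman_smoother, smoothed_omega

__all__ = [
    "CVConfig",
    "CVResult",
    "kfold_split",
    "predict",
    "pe_metrics",
    "select_lambda",
    "run_cv",
]

_METRICS = ("MSE", "RMSE", "MAE")


def kfold_split(dataset: FunctionalDataset, n_folds: int, seed: int) -> list[np.ndarray]:
    """Random partition of the N = n*T curves into folds of near-equal size.

    Curves are indexed day-major: flat index = t * n_stations + s.
    """
    N = dataset.n_curves
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_folds > N:
        raise ValueError(f"cannot split {N} curves into {n_folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(N)
    return [np.sort(perm[i::n_folds]) for i in range(n_folds)]


def _mask_curves(data: FunctionalDataset, curves: np.ndarray) -> FunctionalDataset:
    masked = data.copy()
    n = data.n_stations
    t_idx, s_idx = np.divmod(curves, n)
    masked.y[t_idx, s_idx, :] = np.nan
    return masked


def _smoothed_omega_field(
    data_masked: FunctionalDataset, beta: np.ndarray, config: EMConfig,
    psi, labels: np.ndarray,
) -> np.ndarray:
    """Random-effect prediction everywhere from the masked training data."""
    T, n, q = data_masked.y.shape
    X = build_design(data_masked, config.basis_mu)
    resid = (data_masked.y.reshape(-1) - X @ beta).reshape(T, n, q)
    omega = np.zeros((T, n, q))
    if not psi.v.any():
        return omega
    for g_idx in _partition_groups(labels):
        system = StateSpaceSystem.build(
            data_masked.coords[g_idx], psi, config.basis_omega, config.basis_sigma,
            data_masked.h_grid,
        )
        sm = kalman_smoother(system, resid[:, g_idx, :])
        omega[:, g_idx, :] = smoothed_omega(system, sm.x_smooth)
    return omega


def predict(
    model: FittedModel,
    data: FunctionalDataset,
    beta: np.ndarray,
    target_curves: np.ndarray,
) -> np.ndarray:
    """Out-of-sample prediction for the target curves, shape (len(targets), q).

    The target curves are masked from the data before smoothing, so their
    random effect is inferred only from the remaining observations.
    """
    target_curves = np.asarray(target_curves, int)
    labels = (
        model.partition_labels
        if model.partition_labels is not None
        else np.zeros(data.n_stations, dtype=int)
    )
    masked = _mask_curves(data, target_curves)
    omega = _smoothed_omega_field(masked, model.beta_mle, model.config, model.psi_mle, labels)
    X = build_design(data, model.config.basis_mu)
    n, q = data.n_stations, data.n_points
    t_idx, s_idx = np.divmod(target_curves, n)
    Xc = X.reshape(data.n_days, n, q, -1)[t_idx, s_idx]  # (ntarget, q, mb)
    return Xc @ beta + omega[t_idx, s_idx]


def pe_metrics(y: np.ndarray, yhat: np.ndarray) -> dict[str, float]:
    """MSE / RMSE / MAE over one fold (normalised by curves x grid points)."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have identical shapes")
    if y.size == 0:
        raise ValueError("empty fold")
    err = y - yhat
    mse = float(np.mean(err**2))
    return {"MSE": mse, "RMSE": float(np.sqrt(mse)), "MAE": float(np.mean(np.abs(err)))}


def select_lambda(
    mean_pe: np.ndarray, se_pe: np.ndarray, lambdas: np.ndarray, rule: str = "min"
) -> float:
    """Grid selection of lambda* under the 'min' or 'one_se' rule.

    Ties in the argmin are broken toward the larger (more parsimonious)
    lambda.  The one-SE rule returns the largest grid lambda whose mean PE
    is within one standard error of the minimum.
    """
    mean_pe = np.asarray(mean_pe, float)
    lambdas = np.asarray(lambdas, float)
    if np.allclose(mean_pe, mean_pe[0]):
        warnings.warn("prediction error is flat across the grid", RuntimeWarning)
        return float(lambdas[-1])
    rev = mean_pe[::-1]
    i_min = mean_pe.size - 1 - int(np.argmin(rev))
    if rule == "min":
        return float(lambdas[i_min])
    if rule == "one_se":
        se = np.asarray(se_pe, float)
        threshold = mean_pe[i_min] + (se[i_min] if se.ndim else float(se))
        ok = np.flatnonzero(mean_pe <= threshold)
        return float(lambdas[ok.max()])
    raise ValueError(f"unknown rule {rule!r}")


@dataclass
class CVConfig:
    """Cross-validation settings.

    ``mode='refit'`` re-estimates the MLE, Hessian and path on each
    training set (faithful but expensive); ``mode='fast'`` reuses the
    full-data quadratic approximation and only re-smooths the random
    effects per fold.
    """

    em: EMConfig = field(default_factory=EMConfig)
    penalty: PenaltySpec = field(default_factory=PenaltySpec)
    n_folds: int = 10
    seed: int = 0
    mode: str = "refit"
    fitted: FittedModel | None = None  # reuse an existing full-data fit (fast mode)


@dataclass
class CVResult:
    lambdas: np.ndarray
    fold_pe: dict[str, np.ndarray]  # metric -> (K_ok, L)
    mean_pe: dict[str, np.ndarray]  # metric -> (L,)
    se_pe: dict[str, np.ndarray]  # metric -> (L,)
    selected: dict[tuple[str, str], float]  # (metric, rule) -> lambda*
    n_folds: int
    n_failed: int
    path: PenaltyPath | None = None


def run_cv(data: FunctionalDataset, config: CVConfig) -> CVResult:
    """Full cross-validation loop over the lambda grid (Algorithm-style).

    Per fold: estimate (or reuse) the quadratic approximation, solve the
    penalised path, predict the held-out curves at every lambda, and score
    the three PE metrics; then average over folds and apply the four
    selection criteria (min / one-SE, each for RMSE and MAE).
    """
    if config.mode not in {"refit", "fast"}:
        raise ValueError("mode must be 'refit' or 'fast'")
    folds = kfold_split(data, config.n_folds, config.seed)
    lambdas = config.penalty.lambdas
    L = lambdas.size
    n, q = data.n_stations, data.n_points

    full_model = None
    full_path = None
    if config.mode == "fast":
        full_model = config.fitted or fit_mle(data, config.em)
        full_path = coefficient_path(full_model, config.penalty)

    X = build_design(data, config.em.basis_mu)
    Xr = X.reshape(data.n_days, n, q, -1)

    per_fold: dict[str, list[np.ndarray]] = {m: [] for m in _METRICS}
    n_failed = 0
    for fold in folds:
        try:
            if config.mode == "fast":
                model, path = full_model, full_path
            else:
                train = _mask_curves(data, fold)
                model = fit_mle(train, config.em)
                path = coefficient_path(model, config.penalty)
            labels = (
                model.partition_labels
                if model.partition_labels is not None
                else np.zeros(n, dtype=int)
            )
            masked = _mask_curves(data, fold)
            omega = _smoothed_omega_field(
                masked, model.beta_mle, model.config, model.psi_mle, labels
            )
            t_idx, s_idx = np.divmod(fold, n)
            y_held = data.y[t_idx, s_idx]  # (nf, q)
            keep = ~np.isnan(y_held)
            X_held = Xr[t_idx, s_idx]  # (nf, q, mb)
            om_held = omega[t_idx, s_idx]
            yhat_all = np.einsum("fqm,lm->lfq", X_held, path.betas) + om_held[None]
            vals = {m: np.empty(L) for m in _METRICS}
            for j in range(L):
                mets = pe_metrics(y_held[keep], yhat_all[j][keep])
                for m in _METRICS:
                    vals[m][j] = mets[m]
            for m in _METRICS:
                per_fold[m].append(vals[m])
        except Exception as exc:  # noqa: BLE001 - a failed fold is skipped, not fatal
            n_failed += 1
            warnings.warn(f"CV fold failed and was skipped: {exc}", RuntimeWarning)
    if not per_fold["MSE"]:
        raise RuntimeError("all CV folds failed")

    fold_pe = {m: np.vstack(per_fold[m]) for m in _METRICS}
    K_ok = fold_pe["MSE"].shape[0]
    mean_pe = {m: fold_pe[m].mean(axis=0) for m in _METRICS}
    se_pe = {
        m: fold_pe[m].std(axis=0, ddof=1) / np.sqrt(K_ok) if K_ok > 1
        else np.zeros(L)
        for m in _METRICS
    }
    selected = {}
    for m in ("RMSE", "MAE"):
        for rule in ("min", "one_se"):
            selected[(m, rule)] = select_lambda(mean_pe[m], se_pe[m], lambdas, rule)
    return CVResult(
        lambdas=lambdas.copy(),
        fold_pe=fold_pe,
        mean_pe=mean_pe,
        se_pe=se_pe,
        selected=selected,
        n_folds=config.n_folds,
        n_failed=n_failed,
        path=full_path,
    )
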