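"""Monte-Carlo study harness: simulate -> fit -> path -> cross-validate.

Replicates the full selection pipeline over independent draws of a
simulation setting and aggregates coefficient distributions, selected
penalties and prediction-error curves.  The desk-scale defaults (tens of
replications, a reduced lambda grid, 5-fold fast-mode CV) keep a study in
the minutes range; the full-scale profile (hundreds of replications, the
101-point grid, 10-fold refit CV) reproduces the cluster-scale experiment
and is selected with ``full_scale=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cv_selection import CVConfig, run_cv
from .estimator import EMConfig, fit_mle
from .penalty import PenaltySpec, coefficient_path, lambda_grid
from .simulator import SimulationSetting, simulate

__all__ = ["StudyProfile", "MCSummary", "run_mc_study"]

_CRITERIA = (("RMSE", "min"), ("MAE", "min"), ("RMSE", "one_se"), ("MAE", "one_se"))


@dataclass
class StudyProfile:
    """Resource profile of a Monte-Carlo study."""

    n_reps: int = 50
    n_folds: int = 5
    cv_mode: str = "fast"
    lambdas: np.ndarray = field(
        default_factory=lambda: lambda_grid(1e-5, 0.5, 20)  # 21 values with 0
    )
    em: EMConfig = field(default_factory=EMConfig)

    @classmethod
    def full_scale(cls) -> "StudyProfile":
        return cls(n_reps=500, n_folds=10, cv_mode="refit", lambdas=lambda_grid())


@dataclass
class MCSummary:
    """Aggregated Monte-Carlo results."""

    setting_name: str
    lambdas: np.ndarray
    n_reps: int
    n_failed: int
    selected: dict[tuple[str, str], np.ndarray]  # criterion -> per-rep lambda*
    beta_at_zero: np.ndarray  # (R, mb) MLE coefficients
    beta_at_min: np.ndarray  # (R, mb) at lambda*_min,RMSE
    beta_at_one_se: np.ndarray  # (R, mb) at lambda*_1se,RMSE
    mean_path: np.ndarray  # (L, mb) coefficient means across replications
    mean_pe: dict[str, np.ndarray]  # metric -> (L,) mean CV curve across reps
    se_pe: dict[str, np.ndarray]
    zero_freq_one_se: np.ndarray  # (mb,) share of reps with an exact zero

    def coefficient_table(self) -> pd.DataFrame:
        """Box-plot statistics of the coefficients under the three solutions."""
        rows = []
        for label, arr in (
            ("mle", self.beta_at_zero),
            ("lambda_min_rmse", self.beta_at_min),
            ("lambda_1se_rmse", self.beta_at_one_se),
        ):
            q = np.percentile(arr, [25, 50, 75], axis=0)
            for j in range(arr.shape[1]):
                rows.append(
                    {
                        "solution": label, "coefficient": j,
                        "mean": arr[:, j].mean(), "sd": arr[:, j].std(ddof=1),
                        "q25": q[0, j], "median": q[1, j], "q75": q[2, j],
                        "zero_share": float(np.mean(arr[:, j] == 0.0)),
                    }
                )
        return pd.DataFrame(rows)

    def pe_table(self) -> pd.DataFrame:
        rows = []
        for m, curve in self.mean_pe.items():
            for lam, val, se in zip(self.lambdas, curve, self.se_pe[m]):
                rows.append({"metric": m, "lambda": lam, "mean_pe": val, "se": se})
        return pd.DataFrame(rows)


def run_mc_study(
    setting: SimulationSetting,
    n_reps: int,
    seed: int,
    profile: StudyProfile | None = None,
) -> MCSummary:
    """Seeded replication loop over the full pipeline.

    Each replication draws a fresh station subset and dataset, fits the
    MLE, solves the coefficient path, and cross-validates the penalty.
    Failed replications are logged, excluded and counted.
    """
    profile = profile or StudyProfile()
    k_mu = setting.basis_mu.n_bases
    mb = (setting.n_covariates + 1) * k_mu
    unpenalized = np.zeros(mb, dtype=bool)
    unpenalized[:k_mu] = True  # functional intercept stays unpenalised
    spec = PenaltySpec(lambdas=profile.lambdas, unpenalized_mask=unpenalized)
    L = profile.lambdas.size

    rep_seeds = np.random.SeedSequence(seed).generate_state(n_reps, dtype=np.uint32)
    sel: dict[tuple[str, str], list[float]] = {c: [] for c in _CRITERIA}
    b_zero, b_min, b_ose = [], [], []
    paths = []
    pe_curves: dict[str, list[np.ndarray]] = {"MSE": [], "RMSE": [], "MAE": []}
    n_failed = 0
    for rs in rep_seeds:
        try:
            data, _truth = simulate(setting, int(rs))
            model = fit_mle(data, profile.em)
            cv = run_cv(
                data,
                CVConfig(
                    em=profile.em, penalty=spec, n_folds=profile.n_folds,
                    seed=int(rs), mode=profile.cv_mode, fitted=model,
                ),
            )
            path = cv.path if cv.path is not None else coefficient_path(model, spec)
            for c in _CRITERIA:
                sel[c].append(cv.selected[c])
            lam_min = cv.selected[("RMSE", "min")]
            lam_ose = cv.selected[("RMSE", "one_se")]
            j_min = int(np.argmin(np.abs(profile.lambdas - lam_min)))
            j_ose = int(np.argmin(np.abs(profile.lambdas - lam_ose)))
            b_zero.append(path.betas[0])
            b_min.append(path.betas[j_min])
            b_ose.append(path.betas[j_ose])
            paths.append(path.betas)
            for m in pe_curves:
                pe_curves[m].append(cv.mean_pe[m])
        except Exception as exc:  # noqa: BLE001
            n_failed += 1
            warnings.warn(f"replication failed and was excluded: {exc}", RuntimeWarning)
    if not b_zero:
        raise RuntimeError("all replications failed")

    beta_ose = np.vstack(b_ose)
    pe_stack = {m: np.vstack(v) for m, v in pe_curves.items()}
    R = beta_ose.shape[0]
    return MCSummary(
        setting_name=setting.name,
        lambdas=profile.lambdas.copy(),
        n_reps=R,
        n_failed=n_failed,
        selected={c: np.asarray(v) for c, v in sel.items()},
        beta_at_zero=np.vstack(b_zero),
        beta_at_min=np.vstack(b_min),
        beta_at_one_se=beta_ose,
        mean_path=np.mean(np.stack(paths), axis=0),
        mean_pe={m: a.mean(axis=0) for m, a in pe_stack.items()},
        se_pe={
            m: a.std(axis=0, ddof=1) / np.sqrt(R) if R > 1 else np.zeros(L)
            for m, a in pe_stack.items()
        },
        zero_freq_one_se=np.mean(beta_ose == 0.0, axis=0),
    )
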