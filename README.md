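# fhdgm — functional hidden dynamic geostatistical models with adaptive-LASSO selection

`fhdgm` implements estimation and variable selection for **functional hidden
dynamic geostatistical models (f-HDGM)**: models for curves observed daily at
a network of monitoring stations — the canonical example being hourly NO₂
concentration profiles y_{s,t}(h) at station s, day t, hour h.  It is aimed
at environmental statisticians and epidemiologists who need to select which
meteorological/land-use covariates (and which parts of the day) actually
drive a pollutant, while accounting for spatiotemporal correlation.

## The model

Each observed curve decomposes as

    y_{s,t}(h) = μ_{s,t}(h) + ω_{s,t}(h) + ε_{s,t}(h),   h ∈ [0, 24]

* **Fixed effects** μ_{s,t}(h) = Σ_j Σ_k X_{s,t,j}(h) B_k(h) β_{jk} — a
  functional linear predictor: every regressor (j = 0 is the intercept,
  X_0 ≡ 1) has a coefficient *curve* spanned by K_μ basis functions
  (B-splines or periodic Fourier bases).
* **Random effects** ω_{s,t}(h) = Σ_k B_{k,ω}(h) z_{s,t,k} — a station-level
  latent state z_{s,t} following a vector AR(1), z_{s,t} = G z_{s,t-1} + η_{s,t},
  with spatially correlated innovations Cov(η) built from the exponential
  correlation ρ(d, θ) = exp(−d/θ) (d in km, one variance v_k and range θ_k
  per component).
* **Measurement error** ε with variance profile σ²(h) on its own basis.

Estimation is in three phases:

1. **MLE** of {β, ψ} (ψ = {G, θ, v, σ²}) by an ECM algorithm whose E-step is
   the Kalman smoother of the induced linear-Gaussian state space; the
   log-likelihood is non-decreasing across iterations.
2. **Hessian** H of the marginal log-likelihood in β at the MLE (exact,
   via the innovations decomposition — the marginal model is Gaussian in β).
3. **Adaptive LASSO** on the local quadratic approximation:

       β(λ) = argmin −½ (β−β̂)ᵀ H (β−β̂) + N λ ‖w ∘ β‖₁,
       w_i = |β̂_i|^(−γ), γ = 1 (intercept block unpenalised)

   solved exactly by coordinate descent (a BFGS active-set backend is
   available) along a 101-point grid λ ∈ {0} ∪ [10⁻⁵, 0.5], with λ chosen by
   K-fold cross-validation over whole curves under four criteria
   (argmin / one-standard-error rule, each for RMSE and MAE).

A simulator reproduces the three standard Monte-Carlo designs (independent
data; spatiotemporal correlation; spatiotemporal correlation plus
cross-correlated covariates) and their oracle prediction-error reference
bounds, and a study harness runs the full simulate → fit → path → CV
pipeline over replications.

## Worked example

```python
import numpy as np
from fhdgm import (
    CVConfig, EMConfig, PenaltySpec, SimulationSetting,
    fit_mle, lambda_grid, run_cv, simulate,
)

setting = SimulationSetting.preset("III", n_stations=10, n_days=120)
data, truth = simulate(setting, seed=42)
model = fit_mle(data, EMConfig())
print(f"log-likelihood {model.loglik:.1f} after {model.n_iter} EM iterations")
print("diag(G) =", np.round(model.psi_mle.g_diag, 3))
print("theta   =", np.round(model.psi_mle.theta, 1), "km")
print("sigma^2 =", np.round(model.psi_mle.sigma2_coeffs, 3))

unpen = np.zeros(28, bool); unpen[:7] = True   # intercept block unpenalised
spec = PenaltySpec(lambdas=lambda_grid(1e-5, 0.5, 40), unpenalized_mask=unpen)
cv = run_cv(data, CVConfig(em=model.config, penalty=spec, n_folds=5,
                           seed=42, mode="fast", fitted=model))
lam_1se = cv.selected[("RMSE", "one_se")]
print(f"lambda*_min,RMSE = {cv.selected[('RMSE','min')]:.2e}, "
      f"lambda*_1se,RMSE = {lam_1se:.2e}")
j = int(np.argmin(np.abs(cv.lambdas - lam_1se)))
print("covariate 1 coefficients at the one-SE penalty:",
      np.round(cv.path.betas[j].reshape(4, 7)[1], 3))
```

prints

```
log-likelihood -45312.5 after 5 EM iterations
diag(G) = [0.847 0.852 0.855]
theta   = [39.2 49.5 58.6] km
sigma^2 = [1.002]
lambda*_min,RMSE = 0.00e+00, lambda*_1se,RMSE = 2.36e-02
covariate 1 coefficients at the one-SE penalty: [ 0.911  1.953  0.658  1.173 -0.    -0.     0.   ]
```

The data were generated with diag(G) = 0.85, θ = 50 km, σ² = 1 and the
coefficient pattern (1,1,1,1,0,0,0) for every covariate.  The EM recovers
the dependence parameters closely; at the one-SE penalty the three true-zero
coefficients (bases 5–7) are detected *exactly* zero, while the unit
coefficients stay active (their individual values wobble because the
covariates are cross-correlated up to 0.9 — their sum over overlapping
bases, i.e. the functional coefficient itself, is much more stable).

## Command line

A thin CLI wraps the library for shell pipelines — each subcommand takes
`--config` (YAML), `--seed` and `--out`, and writes a run manifest:

```
fhdgm simulate  --config cfg.yaml --out out/sim      # data + truth tables
fhdgm reference --config cfg.yaml --out out/ref      # oracle PE bounds
fhdgm fit       --data out/sim/data.csv --out out/fit
fhdgm path      --data out/sim/data.csv --out out/path
fhdgm cv        --data out/sim/data.csv --out out/cv
fhdgm mc-study  --config cfg.yaml --out out/study [--full-scale]
```

Data interchange is plain long-format CSV with columns
`station_id, lon, lat, t, h, y, x1..xp` (blank `y` = missing).

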