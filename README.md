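# mdqr — minimum-distance quantile regression for spatial panels

`mdqr` estimates quantile-regression models for spatial autoregressive
(SAR) panel data with individual fixed effects,

```
Q_tau(y_it | D_it, X_it, i) = rho(tau) * D_it + X_it' beta(tau) + eta_i(tau),
D_it = sum_j w_ij * y_jt,
```

where `W = (w_ij)` is a known spatial weight matrix and the spatial lag
`D_it` is endogenous by construction.  It is aimed at econometricians and
applied researchers working with moderately long panels (tens of units,
tens to hundreds of periods) who want distributional (quantile-level)
effects rather than conditional means.

Three estimators are provided:

* **MDQR** — per-unit time-series quantile regressions of `y` on
  `[D, X, 1]`, combined across units by inverse-covariance
  (minimum-distance) weighting,
  `theta_hat = (sum_i V_i^-1)^-1 sum_i V_i^-1 theta_i`.  Fast, but biased:
  the endogeneity of `D` is not corrected.
* **IV-MDQR** — the instrumental-variable version.  For each unit and
  each candidate `rho_j` on a finite grid, the quantile regression of
  `y - rho_j D` on `[X, 1, omega]` is fitted; the coefficient
  `gamma(rho_j)` on the instrument `omega` is driven to zero exactly at
  the true spatial coefficient, so `rho_i = argmin_j ||gamma_i(rho_j)||`.
  Per-unit sandwich covariances `V~_i = J_i^-1 S_i J_i^-T` (Powell kernel
  density at zero, Hall–Sheather bandwidth) weight the same
  minimum-distance combination, and `sqrt(NT)(theta_hat - theta) ->
  N(0, V~)` drives the reported confidence intervals.
* **IV-FEQR** — the pooled fixed-effects IVQR comparison estimator (all
  unit intercepts estimated jointly in one grid-profiled program).

All quantile regressions run on a batched Frisch–Newton interior-point
solver, so full Monte Carlo studies (hundreds of replications, thousands
of per-unit fits each) run in minutes on one core.

## Worked example

```python
import numpy as np
import mdqr

# the block (group-interaction) weight matrix: 50 units in groups of 10
w = mdqr.build_block_weights(50)

# simulate a homoscedastic SAR panel: rho=0.5, beta=1, T=50
rng = np.random.default_rng(0)
params = mdqr.ModelParams(rho=0.5, beta=np.array([1.0]),
                          eta=rng.standard_normal(50))
panel = mdqr.generate_panel(params, w, n_periods=50, tau=0.5,
                            design="homoscedastic", seed=rng)
inst = mdqr.make_instruments(panel, w, "spatial_lag_X")
spec = mdqr.QuantileModelSpec(tau=0.5)

iv = mdqr.fit_iv_mdqr(panel, w, inst, spec)
md = mdqr.fit_mdqr(panel, w, spec)
print("IV-MDQR:", iv.theta_hat.round(4))
print("MDQR   :", md.theta_hat.round(4))
print("95% CI :", mdqr.confidence_intervals(iv).round(4).tolist())
```

Output:

```
IV-MDQR: [0.5093 1.0297]
MDQR   : [0.6313 1.0111]
95% CI : [[0.4047, 0.6139], [0.9593, 1.1]]
```

The uncorrected MDQR overshoots the true `rho = 0.5` by about `0.13`
(the endogeneity bias of the spatial lag), while IV-MDQR lands within a
grid step of the truth; the covariate coefficient `beta = 1` is recovered
by both.  The intervals are the normal-theory bands `theta_k ±
1.96 sqrt(V_kk / NT)`.

The same works from the shell:

```
mdqr simulate --N 50 --T 50 --seed 0 --out panel.csv --weights-out w.csv
mdqr fit --panel panel.csv --weights w.csv --method iv-mdqr --tau 0.5
mdqr sweep --panel panel.csv --weights w.csv --taus 0.25,0.5,0.75
mdqr mc --reps 200 --seed 7 --out table.csv
```

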