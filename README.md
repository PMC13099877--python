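# dlnmm — distributed-lag nonlinear count models with random intercepts

`dlnmm` is a Python toolkit for modelling weekly environmental health
panels: counts of respiratory hospital discharges per climatic subregion
against lagged climatic exposures (temperature, precipitation, relative
humidity, aerosol optical depth).  It is aimed at environmental
epidemiologists and biostatisticians who need the full workflow around
such data — exposure interpolation, lag selection, model fitting, model
ranking and risk summaries — in one tested package.

## The model

Counts `y_it` (subregion `i`, week `t`) follow a Poisson, negative
binomial, or zero-inflated count kernel with mean

    log mu_it = beta0 + sum_v s_v(x_vit) + gamma' D_t + b_i + log N_it

where each exposure enters through a DLNM **cross-basis**

    s_v(x_t) = sum_{l=0}^{L_v} sum_{j,k} b_j(x_{t-l}) h_k(l) beta_jk,

with natural cubic spline bases `b_j` over the exposure and `h_k` over the
lag dimension (3 df each, quantile knots), `D_t` 51 week-of-year dummies,
`b_i ~ N(0, sigma_b^2)` a subregional random intercept, and `log N_it` a
population offset.  Zero inflation adds an intercept-only structural-zero
probability `pi`.  Estimation is exact maximum marginal likelihood via
adaptive Gauss–Hermite quadrature with analytic gradients; see
`docs/methods.md` for the details and numerical conventions.

Around the model the package provides:

* `dlnmm.simulate` — a generative ZINB-DLNM simulator (20 y × 52 w panels,
  seasonal AR(1) exposures, known truth) for end-to-end validation;
* `dlnmm.interpolate` — inverse-distance-weighted aggregation of gappy
  gridded exposures to subregion centroids (`w_ij = d_ij^-p`, `p = 1`);
* `dlnmm.screening` — per-lag dependence screening (Pearson, distance
  correlation, mutual information) with permutation tests and the
  "largest lag where ≥ 2 of 3 are significant" rule (scan bound 14 weeks);
* `dlnmm.selection` — MAE/RMSE/AIC/BIC and OECD-style composite scores
  (min-max and z-score normalization) for ranking candidate models;
* `dlnmm.effects` — relative-risk surfaces RR(x, l), significance windows,
  and cumulative incidence rate ratios for percentile contrasts;
* `dlnmm.pipeline` / the `dlnmm` CLI — a seeded, manifest-logged
  simulate → screen → fit → score → effects run.

## Worked example

Simulate a four-subregion region with known truth, fit the zero-inflated
negative binomial DLNM with a random intercept, and summarize the humidity
effect:

```python
from dlnmm import (SimConfig, simulate_exposures, simulate_counts,
                   default_crossbasis_specs, default_truth, DLNMCountModel)

cfg = SimConfig(n_subregions=4, n_weeks=10 * 52, seed=42)
exposures = simulate_exposures(cfg)
specs = default_crossbasis_specs(exposures,
                                 max_lags={"temperature": 6, "humidity": 4},
                                 names=["temperature", "humidity"])
truth = default_truth(specs, exposures, n_subregions=4, seed=42, pi=0.05)
counts = simulate_counts(exposures, truth, specs, seed=43)

model = DLNMCountModel.from_panels(counts, exposures, specs=specs,
                                   family="zinb", random_intercept=True)
res = model.fit()
print(res.summary(max_rows=4))
print(res.percentile_contrasts("humidity").round(3).to_string(index=False))
```

Output:

```
DLNM count model  family=ZINB  random intercept (4 groups)
nobs=2056  llf=-7316.913  AIC=14779.826  BIC=15190.707  converged=True
------------------------------------------------------------------------
param                       estimate     std err              [95.0% CI]
intercept                   -13.6211      5.8678    -25.1218     -2.1204
cb_temperature_x0_l0         -0.0271      0.0429     -0.1112      0.0571
cb_temperature_x0_l1          0.0253      0.0322     -0.0378      0.0884
cb_temperature_x0_l2         -0.0053      0.0068     -0.0187      0.0081
... (69 more rows)
natural scale: kappa=2.0351  pi=0.0472  sigma_b=0.1588

exposure   contrast   IRR  CI_low  CI_high     p
humidity p95 vs p50 1.383   1.177    1.625 0.000
humidity  p5 vs p50 0.762   0.644    0.902 0.002
```

The fit recovers the generative dispersion (`kappa = 2.04` vs a true 2.0)
and structural-zero share (`pi = 0.047` vs 0.05).  The contrast table reads
as in the epidemiological literature: weeks at the 95th humidity percentile
carry a 38% higher cumulative discharge rate than median-humidity weeks
(IRR 1.383, 95% CI 1.177–1.625), while dry weeks at the 5th percentile are
protective (IRR 0.762).

The same workflow runs from the shell:

```bash
dlnmm run-all --output-dir my_run --seed 7   # simulate, screen, fit 8
                                             # candidate families, score,
                                             # write effect summaries
```

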