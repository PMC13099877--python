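"""Model ranking: accuracy metrics, composite scores, residual diagnostics.

Candidate models for a region are compared on four goodness-of-fit
metrics — MAE, RMSE, AIC, BIC, all "smaller is better" — aggregated into
two composite indicators in the OECD composite-indicator spirit:

* min-max score:  ``z1_ij = 1 - (m_ij - min_j) / (max_j - min_j)``,
* z-score:        ``z2_ij = -(m_ij - mean_j) / sd_j``  (sample SD, n-1),

each averaged with equal weights over the four metrics, so higher is
better for both.  Normalization is within a region's model set.  A
Pearson correlation between the two composite columns serves as the
sensitivity check of the ranking (a strong linear association means the
ranking does not hinge on the normalization choice).

The package ships a reference benchmark table
(``data/regional_fit_benchmark.csv``) of these four metrics and both
printed composite scores for 47 candidate count models fitted to weekly
respiratory hospital-discharge series across six peripheral climatic
regions of Costa Rica; it pins down the scoring conventions (notably the
n-1 standard deviation) in the tests.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "accuracy_metrics",
    "information_criteria",
    "composite_scores",
    "score_sensitivity",
    "residual_acf",
    "load_benchmark_metrics",
]

METRICS = ("mae", "rmse", "aic", "bic")


def accuracy_metrics(y, y_hat) -> dict:
    """MAE and RMSE over all (subregion, week) cells."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if y.size == 0 or y.size != y_hat.size:
        raise ValueError("inputs must be non-empty and of equal length")
    err = y - y_hat
    return {"mae": float(np.mean(np.abs(err))), "rmse": float(np.sqrt(np.mean(err**2)))}


def information_criteria(results) -> dict:
    """AIC and BIC of a fitted model (q counts all estimated parameters)."""
    return {"aic": float(results.aic), "bic": float(results.bic)}


def composite_scores(
    table: pd.DataFrame,
    metrics=METRICS,
    group_col: str | None = None,
) -> pd.DataFrame:
    """Min-max and z-score composites per model.

    ``table`` holds one row per candidate model with the metric columns;
    with ``group_col`` (e.g. region) normalization runs within each group.
    A degenerate metric (all models equal, so no ranking information) maps
    to z1 = 1 and z2 = 0 for every model.

    Returns a copy of the input with per-metric ``z1_*``/``z2_*`` columns
    and the two composites ``minmax_score``/``zscore_score``.
    """
    metrics = list(metrics)
    missing = [m for m in metrics if m not in table.columns]
    if missing:
        raise ValueError(f"metric columns missing from table: {missing}")
    if not np.isfinite(table[metrics].to_numpy(float)).all():
        raise ValueError("metric table contains non-finite entries")

    def _score(group: pd.DataFrame) -> pd.DataFrame:
        if len(group) < 2:
            out = group.copy()
            for m in metrics:
                out[f"z1_{m}"], out[f"z2_{m}"] = 1.0, 0.0
            out["minmax_score"], out["zscore_score"] = 1.0, 0.0
            return out
        m = group[metrics].to_numpy(float)
        rng = m.max(axis=0) - m.min(axis=0)
        sd = m.std(axis=0, ddof=1)
        z1 = np.ones_like(m)
        z2 = np.zeros_like(m)
        ok = rng > 0
        z1[:, ok] = 1.0 - (m[:, ok] - m.min(axis=0)[ok]) / rng[ok]
        z2[:, ok] = -(m[:, ok] - m.mean(axis=0)[ok]) / sd[ok]
        out = group.copy()
        for j, name in enumerate(metrics):
            out[f"z1_{name}"] = z1[:, j]
            out[f"z2_{name}"] = z2[:, j]
        out["minmax_score"] = z1.mean(axis=1)
        out["zscore_score"] = z2.mean(axis=1)
        return out

    if group_col is None:
        return _score(table)
    parts = [
        _score(g) for _, g in table.groupby(group_col, sort=False)
    ]
    return pd.concat(parts).loc[table.index]


def score_sensitivity(scores: pd.DataFrame,
                      col1: str = "minmax_score",
                      col2: str = "zscore_score") -> float:
    """Pearson correlation between the two composite-score columns."""
    a = scores[col1].to_numpy(float)
    b = scores[col2].to_numpy(float)
    if a.size < 3:
        raise ValueError("need at least 3 models for the sensitivity check")
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise ValueError("constant score column: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def residual_acf(residuals, max_lag: int = 26) -> dict:
    """Sample autocorrelations with white-noise bounds.

    Returns the ACF at lags 1..max_lag, the +-1.96/sqrt(n) bound, and the
    count of exceedances (about 5% are expected under white noise).
    """
    from statsmodels.tsa.stattools import acf as sm_acf

    residuals = np.asarray(residuals, float)
    if residuals.size <= max_lag + 10:
        raise ValueError("series too short for the requested max_lag")
    rho = sm_acf(residuals, nlags=max_lag, fft=True)[1:]
    bound = 1.96 / np.sqrt(residuals.size)
    return {
        "acf": rho,
        "bound": float(bound),
        "n_exceed": int(np.sum(np.abs(rho) > bound)),
        "max_lag": int(max_lag),
    }


def load_benchmark_metrics() -> pd.DataFrame:
    """The bundled six-region model-fit benchmark table.

    Columns: region, model, mae, rmse, aic, bic, and the two reference
    composite columns ``minmax_score``/``zscore_score`` as printed in the
    benchmark.
    """
    with resources.files("dlnmm.data").joinpath(
        "regional_fit_benchmark.csv"
    ).open() as fh:
        return pd.read_csv(fh)
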