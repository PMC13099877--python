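"""Exploratory lag screening: which lags of an exposure matter.

Before fitting a distributed-lag model, the maximum lag ``L`` of each
exposure is fixed by a dependence scan: at every lag ``l = 0..14`` the
pair ``(x_{t-l}, y_t)`` is scored with three measures — Pearson
correlation (linear dependence), distance correlation and mutual
information (both sensitive to nonlinear dependence) — and each measure's
significance is assessed with a nonparametric permutation test.  ``L`` is
the largest lag at which at least two of the three measures are
significant at level ``alpha``; if no lag qualifies the exposure enters at
lag 0 only.

Distance correlation is computed from double-centered pairwise-distance
matrices (Szekely-Rizzo); mutual information is the plug-in estimate on a
2-D equal-frequency histogram with ``floor(sqrt(n/5))`` bins clamped to
[5, 20].  Permutations shuffle the response i.i.d. by default; a circular
scheme that preserves serial dependence is available as an option.
"""

from __future__ import annotations

import warnings
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "lagged_pairs",
    "lagged_pearson",
    "distance_correlation",
    "mutual_information",
    "default_bins",
    "permutation_pvalue",
    "screen_lags",
    "select_max_lag",
]

SCAN_BOUND = 14  # default upper bound on the lag scan, in weeks


def lagged_pairs(x, y, lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Aligned pairs ``(x_{t-lag}, y_t)`` for a nonnegative lag."""
    if lag < 0:
        raise ValueError("lag must be >= 0")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    if lag == 0:
        return x, y
    return x[:-lag], y[lag:]


def lagged_pearson(x, y, lag: int = 0) -> float:
    """Pearson correlation of ``(x_{t-lag}, y_t)``.

    Raises on constant input, where the correlation is undefined.
    """
    xs, ys = lagged_pairs(x, y, lag)
    if xs.size < 3:
        raise ValueError("need at least 3 overlapping pairs")
    if np.std(xs) == 0.0 or np.std(ys) == 0.0:
        raise ValueError("correlation undefined for a constant series")
    return float(np.corrcoef(xs, ys)[0, 1])


def _centered_distance_matrix(v: np.ndarray) -> np.ndarray:
    d = np.abs(v[:, None] - v[None, :])
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def distance_correlation(x, y) -> float:
    """Sample distance correlation in [0, 1].

    Zero iff the empirical distance covariance vanishes; invariant under
    affine maps of either input.  Zero-variance input returns 0 with a
    warning rather than an error (the measure is degenerate there).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need equal-length inputs with n >= 4")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        warnings.warn("zero-variance input: distance correlation set to 0",
                      stacklevel=2)
        return 0.0
    A = _centered_distance_matrix(x)
    B = _centered_distance_matrix(y)
    dcov2 = (A * B).mean()
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    denom = np.sqrt(dvar_x * dvar_y)
    if denom <= 0.0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / denom))


def default_bins(n: int) -> int:
    """Equal-frequency bin count: floor(sqrt(n / 5)), clamped to [5, 20]."""
    return int(np.clip(np.floor(np.sqrt(n / 5.0)), 5, 20))


def _bin_labels(v: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency bin assignment via ranks (ties broken by order)."""
    ranks = np.argsort(np.argsort(v, kind="stable"), kind="stable")
    return (ranks * bins) // v.size


def _mi_from_labels(bx: np.ndarray, by: np.ndarray, bins: int) -> float:
    joint = np.bincount(bx * bins + by, minlength=bins * bins).astype(float)
    joint /= joint.sum()
    joint = joint.reshape(bins, bins)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    return float(np.sum(joint[nz] * (np.log(joint[nz])
                                     - np.log(np.outer(px, py)[nz]))))


def mutual_information(x, y, bins: int | None = None) -> float:
    """Plug-in mutual information (nats) on an equal-frequency 2-D histogram.

    Symmetric in its arguments and >= 0; the plug-in estimate carries a
    positive finite-sample bias under independence, which the permutation
    test absorbs.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if bins is None:
        bins = default_bins(x.size)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if x.size < 4 * bins:
        raise ValueError(f"need n >= 4*bins = {4 * bins}, got {x.size}")
    return _mi_from_labels(_bin_labels(x, bins), _bin_labels(y, bins), bins)


# ----------------------------------------------------------------------
# permutation inference
# ----------------------------------------------------------------------


def _permutations(n: int, n_perm: int, rng: np.random.Generator, scheme: str):
    if scheme == "iid":
        return [rng.permutation(n) for _ in range(n_perm)]
    if scheme == "circular":
        shifts = rng.integers(1, n, size=n_perm)
        base = np.arange(n)
        return [np.roll(base, int(s)) for s in shifts]
    raise ValueError(f"unknown permutation scheme {scheme!r}")


def permutation_pvalue(
    statistic: Callable[[np.ndarray, np.ndarray], float],
    x,
    y,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    scheme: str = "iid",
) -> float:
    """Two-sided permutation p-value for any dependence statistic.

    Permutes ``y`` only and uses the add-one estimator
    ``p = (1 + #{|stat_perm| >= |stat_obs|}) / (n_perm + 1)``, so p is
    never exactly 0.  Degenerate statistics (NaN) count as exceedances,
    so a statistic that collapses on every permutation yields p = 1.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99 for a stable p-value")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = abs(statistic(x, y))
    hits = 0
    for perm in _permutations(y.size, n_perm, rng, scheme):
        s = statistic(x, y[perm])
        if not np.isfinite(s) or abs(s) >= obs:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def _fast_three_pvalues(xs, ys, n_perm, rng, bins, scheme):
    """Observed values and permutation p-values of all three measures.

    Shares one stream of permutations across the measures and exploits
    that the x-side structures (standardized values, centered distance
    matrix, bin labels) are permutation-invariant.
    """
    n = xs.size
    perms = _permutations(n, n_perm, rng, scheme)

    # Pearson
    sx = (xs - xs.mean()) / xs.std()
    sy = (ys - ys.mean()) / ys.std()
    r_obs = float(np.mean(sx * sy))
    r_hits = sum(1 for p in perms if abs(np.mean(sx * sy[p])) >= abs(r_obs))

    # distance correlation: dvar terms are permutation-invariant
    A = _centered_distance_matrix(xs)
    B = _centered_distance_matrix(ys)
    denom = np.sqrt((A * A).mean() * (B * B).mean())
    d_obs = np.sqrt(max((A * B).mean(), 0.0) / denom) if denom > 0 else 0.0
    d_hits = 0
    for p in perms:
        dcov2 = (A * B[np.ix_(p, p)]).mean()
        if np.sqrt(max(dcov2, 0.0) / denom) >= d_obs:
            d_hits += 1

    # mutual information on fixed bin labels
    bx = _bin_labels(xs, bins)
    by = _bin_labels(ys, bins)
    mi_obs = _mi_from_labels(bx, by, bins)
    mi_hits = sum(
        1 for p in perms if _mi_from_labels(bx, by[p], bins) >= mi_obs
    )

    denom_p = n_perm + 1
    return (
        r_obs, (1 + r_hits) / denom_p,
        d_obs, (1 + d_hits) / denom_p,
        mi_obs, (1 + mi_hits) / denom_p,
    )


def screen_lags(
    x,
    y,
    scan_bound: int = SCAN_BOUND,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    bins: int | None = None,
    scheme: str = "iid",
    exposure: str = "exposure",
) -> pd.DataFrame:
    """Per-lag dependence table for one exposure/response pair.

    Returns one row per lag 0..``scan_bound`` with the three observed
    statistics, their permutation p-values, per-measure significance flags
    at ``alpha`` and the count of significant measures.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size - scan_bound < 30:
        raise ValueError(
            f"series too short: lag {scan_bound} leaves "
            f"{x.size - scan_bound} < 30 overlapping pairs"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for lag in range(scan_bound + 1):
        xs, ys = lagged_pairs(x, y, lag)
        b = bins if bins is not None else default_bins(xs.size)
        r, pr, d, pd_, mi, pmi = _fast_three_pvalues(xs, ys, n_perm, rng, b, scheme)
        rows.append(
            {
                "exposure": exposure,
                "lag": lag,
                "pearson": r,
                "p_pearson": pr,
                "dcor": d,
                "p_dcor": pd_,
                "mi": mi,
                "p_mi": pmi,
            }
        )
    table = pd.DataFrame(rows)
    for m in ("pearson", "dcor", "mi"):
        table[f"sig_{m}"] = table[f"p_{m}"] < alpha
    table["n_significant"] = (
        table[["sig_pearson", "sig_dcor", "sig_mi"]].sum(axis=1).astype(int)
    )
    return table


def select_max_lag(
    x,
    y,
    scan_bound: int = SCAN_BOUND,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    bins: int | None = None,
    scheme: str = "iid",
    return_table: bool = False,
):
    """Maximum lag by the two-of-three rule.

    ``L = max{ lag <= scan_bound : >= 2 of the 3 measures have p < alpha }``,
    or 0 when no lag qualifies (the exposure then enters at lag 0 only).
    """
    table = screen_lags(
        x, y, scan_bound=scan_bound, alpha=alpha, n_perm=n_perm,
        seed=seed, bins=bins, scheme=scheme,
    )
    qualifying = table.loc[table["n_significant"] >= 2, "lag"]
    L = int(qualifying.max()) if not qualifying.empty else 0
    return (L, table) if return_table else L
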