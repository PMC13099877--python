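"""Inverse-distance-weighted aggregation of gridded exposures.

Satellite retrievals of humidity and aerosol optical depth arrive on a
grid with gaps; the weekly subregional exposure is their inverse-distance
weighted average at the subregion centroid,

    Xhat_it = sum_j w_ij X_jt / sum_j w_ij,    w_ij = d_ij^(-p),

over the grid cells with a non-missing value that week.  Distances are
planar Euclidean on the provided coordinates (project beforehand if
needed); the decay exponent defaults to ``p = 1``.  A centroid coinciding
with a grid cell (d = 0) returns that cell's value exactly — the limit of
the weight formula.  Weeks with no usable cell yield NaN, an explicit
missing marker, never a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["IdwSpec", "idw_interpolate", "interpolate_panel"]


@dataclass
class IdwSpec:
    """Decay exponent and subregion centroids for IDW interpolation."""

    centroids: dict[str, tuple[float, float]] = field(default_factory=dict)
    power: float = 1.0

    def __post_init__(self):
        if not (np.isfinite(self.power) and self.power > 0):
            raise ValueError(f"power must be finite and > 0, got {self.power}")
        for k, (x, y) in self.centroids.items():
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError(f"centroid for {k!r} has non-finite coordinates")


def _idw_values(values: np.ndarray, dist: np.ndarray, power: float) -> float:
    ok = np.isfinite(values)
    if not ok.any():
        return np.nan
    values, dist = values[ok], dist[ok]
    if values.size == 1:
        return float(values[0])
    zero = dist == 0.0
    if zero.any():
        return float(values[zero][0])  # exact-value limit convention
    w = dist ** (-power)
    return float(np.sum(w * values) / np.sum(w))


def idw_interpolate(
    grid: pd.DataFrame,
    spec: IdwSpec,
    subregion: str,
    week: int,
) -> float:
    """IDW estimate for one subregion and week.

    ``grid`` needs columns ``x``, ``y``, ``week``, ``value`` (NaN =
    missing).  Returns NaN when every cell is missing that week.  The
    result always lies within [min, max] of the contributing values.
    """
    if subregion not in spec.centroids:
        raise KeyError(f"no centroid defined for subregion {subregion!r}")
    cx, cy = spec.centroids[subregion]
    g = grid[grid["week"] == week]
    if g.empty:
        return np.nan
    dist = np.hypot(g["x"].to_numpy(float) - cx, g["y"].to_numpy(float) - cy)
    return _idw_values(g["value"].to_numpy(float), dist, spec.power)


def interpolate_panel(
    grid: pd.DataFrame,
    spec: IdwSpec,
    weeks=None,
    value_name: str = "value",
) -> pd.DataFrame:
    """IDW series for every centroid: long (subregion, week, value) panel.

    Vectorized over weeks; cells missing in a given week drop out of both
    sums for that week only.
    """
    if weeks is None:
        weeks = np.sort(grid["week"].unique())
    weeks = np.asarray(weeks)

    # pivot to (cell x week) once; cells keep fixed coordinates
    cells = grid.drop_duplicates("cell").sort_values("cell")
    wide = grid.pivot_table(
        index="cell", columns="week", values="value", dropna=False
    ).reindex(index=cells["cell"], columns=weeks)
    V = wide.to_numpy(float)  # (n_cells, n_weeks)
    xs = cells["x"].to_numpy(float)
    ys = cells["y"].to_numpy(float)

    frames = []
    for sub, (cx, cy) in spec.centroids.items():
        dist = np.hypot(xs - cx, ys - cy)
        if np.any(dist == 0.0):
            j = int(np.argmin(dist))
            est = V[j].copy()
            # cell at the centroid may itself be missing; fall back to IDW
            gaps = ~np.isfinite(est)
            if gaps.any():
                est[gaps] = _masked_idw(V[:, gaps], dist, spec.power, exclude=j)
        else:
            est = _masked_idw(V, dist, spec.power)
        frames.append(pd.DataFrame({"subregion": sub, "week": weeks, value_name: est}))
    return pd.concat(frames, ignore_index=True)


def _masked_idw(V, dist, power, exclude=None):
    w = dist.astype(float) ** (-power)
    if exclude is not None:
        w = w.copy()
        w[exclude] = 0.0
    ok = np.isfinite(V)
    wm = np.where(ok, w[:, None], 0.0)
    num = np.nansum(wm * np.where(ok, V, 0.0), axis=0)
    den = wm.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0.0] = np.nan
    return out
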