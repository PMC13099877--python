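"""Natural cubic spline bases and the exposure-lag cross-basis.

The cross-basis is the design-matrix realization of a distributed-lag
nonlinear term

    s(x_t) = sum_{l=0}^{L} sum_j sum_k  b_j(x_{t-l}) * h_k(l) * beta_{jk},

where ``b_j`` are spline basis functions over the exposure dimension and
``h_k`` spline basis functions over the integer lag dimension.  Multiplying
the cross-basis matrix by the flattened coefficient array ``beta_{jk}``
reproduces the triple sum exactly, which is the invariant the tests pin
down against a brute-force oracle.

The spline family is the natural (restricted) cubic spline: piecewise cubic,
C2-continuous, and linear beyond the boundary knots.  Interior knots default
to equally spaced quantiles of the observed values; boundary knots to the
observed extremes.  The exposure basis omits the constant function (the
model carries its own intercept); the lag basis includes it so that
lag-constant effects are representable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "natural_spline_basis",
    "quantile_knots",
    "CrossBasisSpec",
    "CrossBasisMatrix",
    "cross_basis",
]


def quantile_knots(values: np.ndarray, n_interior: int) -> np.ndarray:
    """Interior knots at equally spaced quantiles of ``values``.

    With ``n_interior = m`` the probabilities are 1/(m+1), ..., m/(m+1).
    """
    values = np.asarray(values, dtype=float)
    if n_interior <= 0:
        return np.empty(0)
    probs = np.arange(1, n_interior + 1) / (n_interior + 1)
    return np.quantile(values, probs)


def _truncated_cubic(x: np.ndarray, knot: float) -> np.ndarray:
    return np.maximum(x - knot, 0.0) ** 3


def natural_spline_basis(
    values: Sequence[float],
    df: int,
    interior_knots: Sequence[float] | None = None,
    boundary_knots: tuple[float, float] | None = None,
    include_intercept: bool = False,
) -> np.ndarray:
    """Evaluate a natural cubic spline basis at ``values``.

    Parameters
    ----------
    values : array-like
        Points at which to evaluate the basis.
    df : int
        Number of basis columns returned.  Without an intercept, ``df``
        columns require ``df - 1`` interior knots; with an intercept,
        ``df - 2`` interior knots (``df = 1`` returns the constant column,
        ``df = 2`` the constant and identity).
    interior_knots, boundary_knots : optional
        Explicit knots.  When omitted, interior knots sit at equally spaced
        quantiles of ``values`` and boundary knots at the extremes.
    include_intercept : bool
        Whether the constant function is part of the basis.

    Returns
    -------
    ndarray of shape ``(len(values), df)``.

    Notes
    -----
    Uses the truncated-power representation of the natural spline: beyond
    the boundary knots every column is exactly linear (zero second
    derivative), which implies natural linear extrapolation when the basis
    is later evaluated outside the boundary knots.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")

    if include_intercept:
        if df == 1:
            return np.ones((x.size, 1))
        n_interior = df - 2
    else:
        n_interior = df - 1

    if boundary_knots is None:
        boundary_knots = (float(np.min(x)), float(np.max(x)))
    lo, hi = map(float, boundary_knots)
    if not hi > lo:
        raise ValueError(f"boundary knots must be increasing, got ({lo}, {hi})")

    if interior_knots is None:
        inner = quantile_knots(x, n_interior)
    else:
        inner = np.asarray(interior_knots, dtype=float)
    if inner.size != n_interior:
        raise ValueError(
            f"df={df} (intercept={include_intercept}) requires {n_interior} "
            f"interior knots, got {inner.size}"
        )

    knots = np.concatenate([[lo], inner, [hi]])
    if np.any(np.diff(knots) <= 0):
        raise ValueError(f"knots must be strictly increasing, got {knots}")

    cols = [np.ones_like(x), x]
    k_last = knots[-1]
    k_penult = knots[-2]

    def d(knot: float) -> np.ndarray:
        return (_truncated_cubic(x, knot) - _truncated_cubic(x, k_last)) / (
            k_last - knot
        )

    d_penult = d(k_penult)
    for knot in knots[:-2]:
        cols.append(d(knot) - d_penult)

    basis = np.column_stack(cols)
    if not include_intercept:
        basis = basis[:, 1:]
    assert basis.shape[1] == df
    return basis


@dataclass
class CrossBasisSpec:
    """Frozen description of one exposure's cross-basis.

    Stores the knots actually used so a fitted model can be re-evaluated on
    new exposure values (risk surfaces, percentile contrasts) without access
    to the training data.  The lag basis always includes the constant
    function; its effective degrees of freedom are capped at ``max_lag + 1``
    since only that many distinct integer lags exist.
    """

    name: str
    max_lag: int
    exposure_df: int = 3
    lag_df: int = 3
    exposure_knots: tuple[float, ...] = field(default=None)  # interior
    exposure_boundary: tuple[float, float] = field(default=None)

    def __post_init__(self) -> None:
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")
        if self.exposure_df < 1 or self.lag_df < 1:
            raise ValueError("spline degrees of freedom must be >= 1")
        if self.exposure_knots is not None:
            self.exposure_knots = tuple(float(k) for k in self.exposure_knots)
        if self.exposure_boundary is not None:
            self.exposure_boundary = tuple(float(k) for k in self.exposure_boundary)

    # ------------------------------------------------------------------
    @classmethod
    def from_data(
        cls,
        name: str,
        values: Sequence[float],
        max_lag: int,
        exposure_df: int = 3,
        lag_df: int = 3,
    ) -> "CrossBasisSpec":
        """Place exposure knots from the pooled observed distribution."""
        values = np.asarray(values, dtype=float)
        inner = quantile_knots(values, exposure_df - 1)
        return cls(
            name=name,
            max_lag=max_lag,
            exposure_df=exposure_df,
            lag_df=lag_df,
            exposure_knots=tuple(inner),
            exposure_boundary=(float(values.min()), float(values.max())),
        )

    # ------------------------------------------------------------------
    @property
    def lag_df_effective(self) -> int:
        return min(self.lag_df, self.max_lag + 1)

    @property
    def n_columns(self) -> int:
        return self.exposure_df * self.lag_df_effective

    def exposure_basis(self, values: Sequence[float]) -> np.ndarray:
        """Evaluate the exposure-dimension basis (no intercept column)."""
        if self.exposure_boundary is None:
            raise ValueError(
                f"spec '{self.name}' has no knots; build it with from_data()"
            )
        return natural_spline_basis(
            values,
            df=self.exposure_df,
            interior_knots=self.exposure_knots,
            boundary_knots=self.exposure_boundary,
            include_intercept=False,
        )

    def lag_basis(self) -> np.ndarray:
        """Evaluate the lag-dimension basis on integer lags 0..L.

        Returns an ``(L + 1, lag_df_effective)`` matrix.  Interior knots sit
        at equally spaced quantiles of the integer lag range.
        """
        lags = np.arange(self.max_lag + 1, dtype=float)
        df = self.lag_df_effective
        if df == 1:
            return np.ones((lags.size, 1))
        if df == 2:
            return np.column_stack([np.ones_like(lags), lags])
        inner = quantile_knots(lags, df - 2)
        return natural_spline_basis(
            lags,
            df=df,
            interior_knots=inner,
            boundary_knots=(float(lags[0]), float(lags[-1])),
            include_intercept=True,
        )

    def column_names(self) -> list[str]:
        return [
            f"cb_{self.name}_x{j}_l{k}"
            for j in range(self.exposure_df)
            for k in range(self.lag_df_effective)
        ]

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "max_lag": self.max_lag,
            "exposure_df": self.exposure_df,
            "lag_df": self.lag_df,
            "exposure_knots": list(self.exposure_knots or ()),
            "exposure_boundary": list(self.exposure_boundary)
            if self.exposure_boundary
            else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CrossBasisSpec":
        return cls(
            name=d["name"],
            max_lag=int(d["max_lag"]),
            exposure_df=int(d["exposure_df"]),
            lag_df=int(d["lag_df"]),
            exposure_knots=tuple(d["exposure_knots"]) or None,
            exposure_boundary=tuple(d["exposure_boundary"])
            if d.get("exposure_boundary")
            else None,
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "CrossBasisSpec":
        return cls.from_dict(json.loads(s))


@dataclass
class CrossBasisMatrix:
    """Cross-basis design columns for one exposure on one series.

    ``matrix[t, j * v_l + k] = sum_l b_j(x_{t0 + t - l}) h_k(l)`` where
    ``t0`` is the index of the first retained week.
    """

    matrix: np.ndarray
    spec: CrossBasisSpec
    first_index: int

    @property
    def column_names(self) -> list[str]:
        return self.spec.column_names()

    def predictor(self, coefs: np.ndarray) -> np.ndarray:
        """Linear predictor contribution for coefficient array ``beta_jk``."""
        coefs = np.asarray(coefs, dtype=float)
        expected = (self.spec.exposure_df, self.spec.lag_df_effective)
        if coefs.shape not in (expected, (self.matrix.shape[1],)):
            raise ValueError(
                f"coefficient shape {coefs.shape} does not match spec {expected}"
            )
        return self.matrix @ coefs.ravel()


def cross_basis(
    x: Sequence[float],
    spec: CrossBasisSpec,
    first_index: int | None = None,
) -> CrossBasisMatrix:
    """Build the cross-basis matrix for one contiguous exposure series.

    Parameters
    ----------
    x : array-like
        The exposure series of a single subregion, in week order.  The
        first ``first_index`` values serve only as lag context (burn-in).
    spec : CrossBasisSpec
        Must carry knots (use :meth:`CrossBasisSpec.from_data`).
    first_index : int, optional
        Index of the first retained week; defaults to ``spec.max_lag`` and
        must be at least that, otherwise early rows would lack lagged
        values and the construction refuses rather than emitting NAs.
    """
    x = np.asarray(x, dtype=float)
    L = spec.max_lag
    if first_index is None:
        first_index = L
    if first_index < L:
        raise ValueError(
            f"first_index={first_index} < max_lag={L}: leading weeks cannot "
            "supply all lagged exposure values"
        )
    n_out = x.size - first_index
    if n_out <= 0:
        raise ValueError(
            f"series of length {x.size} leaves no rows after burn-in {first_index}"
        )

    bx = spec.exposure_basis(x)  # (n_total, v_x)
    H = spec.lag_basis()  # (L+1, v_l)
    v_x, v_l = spec.exposure_df, spec.lag_df_effective

    out = np.zeros((n_out, v_x * v_l))
    t = np.arange(first_index, x.size)
    for lag in range(L + 1):
        b_lagged = bx[t - lag]  # (n_out, v_x)
        # accumulate b_j(x_{t-l}) * h_k(l) into column (j, k)
        out += np.einsum("nj,k->njk", b_lagged, H[lag]).reshape(n_out, -1)
    return CrossBasisMatrix(matrix=out, spec=spec, first_index=first_index)
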