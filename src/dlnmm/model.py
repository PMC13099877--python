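"""Count mixed models with cross-basis terms: the DLNM-GLMM.

The mean model for weekly hospital-discharge counts ``y_it`` of subregion
``i`` at week ``t`` is

    log mu_it = beta0 + sum_v s_v(x_vit; beta_v) + gamma' D_t + b_i + log N_it,

with ``s_v`` the cross-basis term of exposure ``v`` (see :mod:`dlnmm.basis`),
``D_t`` 51 seasonal dummies over a 52-week year, ``b_i ~ N(0, sigma_b^2)`` a
subregional random intercept and ``log N_it`` the population offset.  The
response family is Poisson, negative binomial, or either of their
zero-inflated extensions with an intercept-only structural-zero probability
(:mod:`dlnmm.families`).

Estimation is exact maximum marginal likelihood: the random intercept is
integrated out per subregion by adaptive Gauss-Hermite quadrature (the
quadrature rule is recentred at each subregion's conditional mode and
rescaled by the local curvature), and the marginal likelihood is maximized
by L-BFGS with analytic gradients.  Standard errors come from the observed
information (finite differences of the analytic score).

The public surface follows the statsmodels convention: build a
:class:`DLNMCountModel` from arrays or panels, call :meth:`fit`, and read
estimates, uncertainties and diagnostics off the returned
:class:`DLNMCountResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .basis import CrossBasisSpec, cross_basis
from .families import FAMILIES, loglik_parts

__all__ = [
    "DLNMCountModel",
    "DLNMCountResults",
    "DesignInfo",
    "build_design",
    "seasonal_dummies",
]

_SQRT2 = np.sqrt(2.0)

N_SEASONS = 52  # epidemiological weeks per year; week 1 is the reference


def seasonal_dummies(weeks: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Reference-coded seasonal dummies from 0-based week indices.

    Season = ``week mod 52``; the 51 columns indicate seasons 1..51 with
    season 0 (the first epidemiological week) as reference.
    """
    weeks = np.asarray(weeks, dtype=int)
    season = weeks % N_SEASONS
    D = np.zeros((weeks.size, N_SEASONS - 1))
    for s in range(1, N_SEASONS):
        D[season == s, s - 1] = 1.0
    names = [f"season_{s}" for s in range(1, N_SEASONS)]
    return D, names


@dataclass
class DesignInfo:
    """Fixed-effect design plus everything needed to refit or interpret it."""

    X: np.ndarray
    y: np.ndarray
    offset: np.ndarray
    groups: np.ndarray  # integer codes, sorted blocks
    group_labels: list
    column_names: list[str]
    cb_slices: dict[str, slice] = field(default_factory=dict)
    cb_specs: dict[str, CrossBasisSpec] = field(default_factory=dict)
    index: pd.DataFrame | None = None  # (subregion, week) per row
    exposures: pd.DataFrame | None = None


def build_design(
    counts: pd.DataFrame,
    exposures: pd.DataFrame,
    specs: Sequence[CrossBasisSpec] | None = None,
    exposure_columns: Sequence[str] | None = None,
    seasonal: bool = True,
    count_col: str = "count",
    population_col: str = "population",
) -> DesignInfo:
    """Assemble the fixed-effect design for a region's panel.

    Parameters
    ----------
    counts : DataFrame
        Long panel with ``subregion``, ``week`` (0-based integers,
        contiguous per subregion), the count column and the population at
        risk.  The first retained week of every subregion must leave
        ``max_v L_v`` earlier weeks of exposure data as lag context.
    exposures : DataFrame
        Long panel with ``subregion``, ``week`` and one column per
        exposure; must cover every count week plus the lag context.
    specs : sequence of CrossBasisSpec, optional
        One per exposure entering through a cross-basis.  When None the
        exposures listed in ``exposure_columns`` enter linearly at lag 0
        (the plain GLM variant used as a no-DLNM baseline).
    seasonal : bool
        Include the 51 seasonal dummies.

    Returns
    -------
    DesignInfo
        With columns ordered intercept | cross-bases | seasonal dummies and
        offset ``log(population)``.
    """
    specs = list(specs) if specs is not None else None
    required = {"subregion", "week", count_col, population_col}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts panel lacks columns {sorted(missing)}")

    counts = counts.sort_values(["subregion", "week"]).reset_index(drop=True)
    exposures = exposures.sort_values(["subregion", "week"]).reset_index(drop=True)

    sub_labels = list(pd.unique(counts["subregion"]))
    max_lag = max((s.max_lag for s in specs), default=0) if specs else 0

    X_blocks: list[np.ndarray] = []
    col_names: list[str] = ["intercept"]
    cb_slices: dict[str, slice] = {}

    rows_y, rows_off, rows_group = [], [], []
    per_sub_cb: list[list[np.ndarray]] = []
    per_sub_lin: list[np.ndarray] = []

    for gi, sub in enumerate(sub_labels):
        c = counts[counts["subregion"] == sub]
        e = exposures[exposures["subregion"] == sub]
        if e.empty:
            raise ValueError(f"no exposure rows for subregion {sub!r}")
        cw = c["week"].to_numpy()
        ew = e["week"].to_numpy()
        if np.any(np.diff(cw) != 1) or np.any(np.diff(ew) != 1):
            raise ValueError(f"weeks not contiguous for subregion {sub!r}")
        first = cw[0] - ew[0]
        if first < max_lag:
            raise ValueError(
                f"subregion {sub!r}: only {first} exposure weeks precede the "
                f"first count week but max lag is {max_lag}"
            )
        if cw[-1] > ew[-1]:
            raise ValueError(
                f"subregion {sub!r}: count weeks extend beyond exposure weeks"
            )
        n_keep = cw.size
        rows_y.append(c[count_col].to_numpy(dtype=float))
        rows_off.append(np.log(c[population_col].to_numpy(dtype=float)))
        rows_group.append(np.full(n_keep, gi))

        if specs is not None:
            blocks = []
            for spec in specs:
                series = e[spec.name].to_numpy(dtype=float)[: first + n_keep]
                cb = cross_basis(series, spec, first_index=first)
                blocks.append(cb.matrix)
            per_sub_cb.append(blocks)
        elif exposure_columns:
            lin = e.loc[e["week"].isin(cw), list(exposure_columns)].to_numpy(float)
            per_sub_lin.append(lin)

    y = np.concatenate(rows_y)
    offset = np.concatenate(rows_off)
    groups = np.concatenate(rows_group)
    n = y.size

    X_blocks.append(np.ones((n, 1)))
    pos = 1
    if specs is not None:
        for si, spec in enumerate(specs):
            block = np.vstack([per_sub_cb[g][si] for g in range(len(sub_labels))])
            X_blocks.append(block)
            cb_slices[spec.name] = slice(pos, pos + block.shape[1])
            col_names.extend(spec.column_names())
            pos += block.shape[1]
    elif exposure_columns:
        block = np.vstack(per_sub_lin)
        X_blocks.append(block)
        for name in exposure_columns:
            cb_slices[name] = slice(pos, pos + 1)
            col_names.append(f"lin_{name}")
            pos += 1

    weeks_all = counts["week"].to_numpy(dtype=int)
    if seasonal:
        D, dnames = seasonal_dummies(weeks_all)
        X_blocks.append(D)
        col_names.extend(dnames)

    X = np.hstack(X_blocks)
    index = counts[["subregion", "week"]].copy()
    return DesignInfo(
        X=X,
        y=y,
        offset=offset,
        groups=groups,
        group_labels=sub_labels,
        column_names=col_names,
        cb_slices=cb_slices,
        cb_specs={s.name: s for s in specs} if specs else {},
        index=index,
        exposures=exposures,
    )


# ======================================================================
# model
# ======================================================================


class DLNMCountModel:
    """Count regression with optional zero inflation and random intercept.

    Parameters
    ----------
    y : array of nonnegative integer counts.
    X : fixed-effect design matrix (include the intercept column).
    offset : additive offset on the log-mean scale (``log N_it``); 0 if None.
    groups : group codes for the random intercept, or None for a model
        without random effects.  At least two groups are required for the
        random-intercept SD to be estimable.
    family : one of ``poisson``, ``negbin``, ``zip``, ``zinb``.
    n_quad : number of adaptive Gauss-Hermite nodes (default 15).

    Notes
    -----
    The parameter vector is ``[beta, log kappa?, logit pi?, log sigma_b?]``
    in that order, with the auxiliary entries present as dictated by the
    family and ``groups``.
    """

    def __init__(
        self,
        y,
        X,
        offset=None,
        groups=None,
        family: str = "poisson",
        n_quad: int = 15,
        column_names: Sequence[str] | None = None,
        design_info: DesignInfo | None = None,
    ):
        self.y = np.asarray(y, dtype=float)
        if np.any(self.y < 0) or np.any(self.y != np.round(self.y)):
            raise ValueError("y must contain nonnegative integers")
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be 2-D with one row per observation")
        self.offset = (
            np.zeros_like(self.y) if offset is None else np.asarray(offset, float)
        )
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}; choose from {list(FAMILIES)}")
        self.family = family
        self.has_kappa = FAMILIES[family]["kappa"]
        self.has_pi = FAMILIES[family]["pi"]
        self.n_quad = int(n_quad)
        self.design_info = design_info

        if groups is None:
            self.groups = None
            self.has_sigma = False
            self._slices = None
        else:
            groups = np.asarray(groups)
            codes, labels = pd.factorize(groups, sort=False)
            order = np.argsort(codes, kind="stable")
            if not np.array_equal(order, np.arange(codes.size)):
                raise ValueError("rows must be sorted by group (contiguous blocks)")
            self.groups = codes
            self.group_labels = list(labels)
            if len(labels) < 2:
                raise ValueError(
                    "random-intercept models need >= 2 groups; pass groups=None"
                )
            bounds = np.flatnonzero(np.diff(codes)) + 1
            starts = np.concatenate([[0], bounds])
            stops = np.concatenate([bounds, [codes.size]])
            self._slices = [slice(a, b) for a, b in zip(starts, stops)]
            self.has_sigma = True

        names = list(column_names) if column_names is not None else None
        if names is None and design_info is not None:
            names = list(design_info.column_names)
        if names is None:
            names = [f"x{j}" for j in range(self.X.shape[1])]
        self.exog_names = names
        self.param_names = list(names)
        if self.has_kappa:
            self.param_names.append("log_kappa")
        if self.has_pi:
            self.param_names.append("logit_pi")
        if self.has_sigma:
            self.param_names.append("log_sigma_b")

        self._z, self._w = np.polynomial.hermite.hermgauss(self.n_quad)
        self._logw = np.log(self._w)
        self._mode_cache = (
            np.zeros(len(self._slices)) if self._slices is not None else None
        )

        # Internal column standardization: raw spline columns live on wildly
        # different scales (cubic terms of the exposure), which cripples the
        # optimizer.  Fit in centered/scaled coordinates, report raw ones.
        mean = self.X.mean(axis=0)
        scale = self.X.std(axis=0)
        const = scale < 1e-12
        mean[const] = 0.0
        scale[const] = 1.0
        if self.X.shape[1] > 0 and np.all(self.X[:, 0] == 1.0):
            mean[0], scale[0] = 0.0, 1.0
            has_const = True
        else:
            has_const = False
        self._col_mean, self._col_scale = mean, scale
        self._Xs = (self.X - mean) / scale
        p = self.X.shape[1]
        # beta_raw = T @ beta_std ; intercept absorbs the centering shifts
        T = np.diag(1.0 / scale)
        if has_const:
            T[0, 1:] = -mean[1:] / scale[1:]
            T[0, 0] = 1.0
        self._T = T
        Tfull = np.eye(self.n_params)
        Tfull[:p, :p] = T
        self._T_full = Tfull
        Tinv = np.diag(scale)
        if has_const:
            Tinv[0, 1:] = mean[1:]
            Tinv[0, 0] = 1.0
        Tinv_full = np.eye(self.n_params)
        Tinv_full[:p, :p] = Tinv
        self._Tinv_full = Tinv_full

    # ------------------------------------------------------------------
    @classmethod
    def from_panels(
        cls,
        counts: pd.DataFrame,
        exposures: pd.DataFrame,
        specs: Sequence[CrossBasisSpec] | None = None,
        family: str = "zinb",
        random_intercept: bool = True,
        seasonal: bool = True,
        exposure_columns: Sequence[str] | None = None,
        n_quad: int = 15,
    ) -> "DLNMCountModel":
        """Build the model from count and exposure panels (see build_design)."""
        info = build_design(
            counts,
            exposures,
            specs=specs,
            exposure_columns=exposure_columns,
            seasonal=seasonal,
        )
        return cls(
            info.y,
            info.X,
            offset=info.offset,
            groups=info.groups if random_intercept else None,
            family=family,
            n_quad=n_quad,
            design_info=info,
        )

    # ------------------------------------------------------------------
    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    def _unpack(self, params):
        p = self.n_fixed
        beta = params[:p]
        i = p
        kappa = pi = sigma = None
        if self.has_kappa:
            kappa = float(np.exp(params[i]))
            i += 1
        if self.has_pi:
            pi = float(special.expit(params[i]))
            i += 1
        if self.has_sigma:
            sigma = float(np.exp(params[i]))
        return beta, kappa, pi, sigma

    # ------------------------------------------------------------------
    def loglike(self, params) -> float:
        return self.loglike_and_score(np.asarray(params, float))[0]

    def score(self, params) -> np.ndarray:
        return self.loglike_and_score(np.asarray(params, float))[1]

    def loglike_and_score(self, params):
        """Marginal log-likelihood and its gradient.

        Without random effects this is a plain sum over observations.  With
        them, each group's intercept is integrated out by adaptive
        Gauss-Hermite quadrature and the gradient is the posterior-weighted
        conditional score evaluated at the quadrature nodes.
        """
        return self._ll_and_score(np.asarray(params, float), self.X)

    def _ll_and_score(self, params, X):
        beta, kappa, pi, sigma = self._unpack(params)
        eta0 = X @ beta + self.offset
        pi_eff = 0.0 if pi is None else pi

        if not self.has_sigma:
            parts = loglik_parts(self.y, eta0, kappa, pi_eff)
            ll = float(parts["logpmf"].sum())
            grad = np.empty(self.n_params)
            grad[: self.n_fixed] = X.T @ parts["d_eta"]
            i = self.n_fixed
            if self.has_kappa:
                grad[i] = parts["d_logkappa"].sum()
                i += 1
            if self.has_pi:
                grad[i] = parts["d_logitpi"].sum()
            return ll, grad

        ll = 0.0
        grad = np.zeros(self.n_params)
        i_kappa = self.n_fixed if self.has_kappa else None
        i_pi = self.n_fixed + (1 if self.has_kappa else 0) if self.has_pi else None
        i_sigma = self.n_params - 1

        for gi, sl in enumerate(self._slices):
            y_g = self.y[sl]
            eta_g = eta0[sl]
            b_hat, curv = self._find_mode(y_g, eta_g, kappa, pi_eff, sigma, gi)
            s_i = 1.0 / np.sqrt(-curv)
            b_nodes = b_hat + _SQRT2 * s_i * self._z

            parts = loglik_parts(
                y_g[:, None], eta_g[:, None] + b_nodes[None, :], kappa, pi_eff
            )
            g_q = parts["logpmf"].sum(axis=0) - 0.5 * b_nodes**2 / sigma**2 - np.log(
                sigma
            ) - 0.5 * np.log(2 * np.pi)
            log_terms = self._logw + g_q + self._z**2
            m = log_terms.max()
            sumexp = np.exp(log_terms - m).sum()
            ll_i = m + np.log(sumexp) + np.log(_SQRT2 * s_i)
            ll += ll_i
            omega = np.exp(log_terms - m) / sumexp

            grad[: self.n_fixed] += X[sl].T @ (parts["d_eta"] @ omega)
            if i_kappa is not None:
                grad[i_kappa] += parts["d_logkappa"].sum(axis=0) @ omega
            if i_pi is not None:
                grad[i_pi] += parts["d_logitpi"].sum(axis=0) @ omega
            grad[i_sigma] += omega @ (b_nodes**2 / sigma**2 - 1.0)
        return float(ll), grad

    def _find_mode(self, y_g, eta_g, kappa, pi, sigma, gi, tol=1e-10, maxiter=60):
        """Newton search for the conditional mode of one group's intercept."""
        b = float(self._mode_cache[gi])
        for _ in range(maxiter):
            parts = loglik_parts(y_g, eta_g + b, kappa, pi)
            g1 = parts["d_eta"].sum() - b / sigma**2
            g2 = parts["d2_eta"].sum() - 1.0 / sigma**2
            if g2 >= -1e-12:  # safeguard: curvature must stay negative
                g2 = -1.0 / sigma**2
            step = -g1 / g2
            step = np.clip(step, -5.0 * sigma, 5.0 * sigma)
            b += step
            if abs(step) < tol:
                break
        parts = loglik_parts(y_g, eta_g + b, kappa, pi)
        curv = parts["d2_eta"].sum() - 1.0 / sigma**2
        if curv >= -1e-12:
            curv = -1.0 / sigma**2
        self._mode_cache[gi] = b
        return b, curv

    # ------------------------------------------------------------------
    def start_params(self) -> np.ndarray:
        """Data-driven starting values.

        Fixed effects from a Poisson GLM without random effects; kappa by
        method of moments on its Pearson residuals; pi from the excess of
        observed zeros over the GLM-predicted zero probability; sigma_b
        starts at 0.1.
        """
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                glm = sm.GLM(
                    self.y, self.X, family=sm.families.Poisson(), offset=self.offset
                ).fit(maxiter=100)
                beta = np.asarray(glm.params, float)
                mu = np.asarray(glm.mu, float)
            except Exception:
                beta = np.zeros(self.n_fixed)
                beta[0] = np.log(self.y.mean() + 0.1) - self.offset.mean()
                mu = np.exp(self.X @ beta + self.offset)

        start = [beta]
        if self.has_kappa:
            excess = np.sum((self.y - mu) ** 2 - mu)
            kappa = np.sum(mu**2) / excess if excess > 0 else 100.0
            kappa = float(np.clip(kappa, 0.05, 1e4))
            start.append([np.log(kappa)])
        if self.has_pi:
            p0_obs = np.mean(self.y == 0)
            p0_pred = float(np.mean(np.exp(-np.minimum(mu, 500))))
            pi0 = (p0_obs - p0_pred) / max(1.0 - p0_pred, 1e-8)
            pi0 = float(np.clip(pi0, 1e-3, 0.5))
            if p0_obs < 0.005:
                warnings.warn(
                    "observed zero fraction < 0.005: the structural-zero "
                    "probability is weakly identified and will be pinned near 0",
                    stacklevel=2,
                )
            start.append([special.logit(pi0)])
        if self.has_sigma:
            start.append([np.log(0.1)])
        return np.concatenate(start)

    # ------------------------------------------------------------------
    def fit(
        self,
        start_params=None,
        maxiter: int = 1000,
        gtol: float = 1e-5,
        compute_vcov: bool = True,
    ) -> "DLNMCountResults":
        """Maximize the (marginal) likelihood; deterministic given the data.

        Non-convergence is flagged on the results object, never silent.
        """
        x0_raw = (
            np.asarray(start_params, float)
            if start_params is not None
            else self.start_params()
        )
        x0 = self._Tinv_full @ x0_raw  # optimize in standardized coordinates
        if self._mode_cache is not None:
            self._mode_cache[:] = 0.0

        bounds = [(None, None)] * self.n_fixed
        if self.has_kappa:
            bounds.append((np.log(1e-3), np.log(1e8)))
        if self.has_pi:
            bounds.append((-14.0, 7.0))
        if self.has_sigma:
            bounds.append((np.log(1e-6), np.log(10.0)))

        def negloglike(p):
            ll, g = self._ll_and_score(p, self._Xs)
            if not np.isfinite(ll):
                return 1e12, np.zeros_like(g)
            return -ll, -g

        res = optimize.minimize(
            negloglike,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": gtol},
        )
        params_std = res.x
        llf, score = self._ll_and_score(params_std, self._Xs)

        vcov_std = None
        if compute_vcov:
            # Newton polish: reuse the observed-information Hessian computed
            # for the vcov to sharpen the L-BFGS solution.
            for _ in range(3):
                H = self._hessian(params_std)
                try:
                    step = np.linalg.solve(-H, score)
                except np.linalg.LinAlgError:
                    break
                for frac in (1.0, 0.5, 0.25, 0.1):
                    cand = params_std + frac * step
                    ll_new, score_new = self._ll_and_score(cand, self._Xs)
                    if np.isfinite(ll_new) and ll_new >= llf:
                        break
                else:
                    break
                params_std, llf, score = cand, ll_new, score_new
                if np.max(np.abs(step)) < 1e-8:
                    break
            vcov_std = self._vcov_from_hessian(self._hessian(params_std))

        params = self._T_full @ params_std
        converged = bool(res.success) or float(np.max(np.abs(score))) < 1e-4 * max(
            1.0, abs(llf)
        )
        if not converged:
            warnings.warn(
                f"optimizer did not converge: {res.message} "
                f"(|score|_max={np.max(np.abs(score)):.3g})",
                stacklevel=2,
            )

        vcov = None
        if vcov_std is not None:
            vcov = self._T_full @ vcov_std @ self._T_full.T
        return DLNMCountResults(
            model=self,
            params=params,
            llf=float(llf),
            vcov=vcov,
            converged=converged,
            optim_message=str(res.message),
            n_iter=int(res.nit),
        )

    def _hessian(self, params_std) -> np.ndarray:
        """Hessian of the log-likelihood via central differences of the score.

        Computed in the standardized design coordinates, where the problem
        is well conditioned.
        """
        p = params_std.size
        H = np.zeros((p, p))
        for j in range(p):
            h = 1e-5 * max(1.0, abs(params_std[j]))
            up = params_std.copy()
            dn = params_std.copy()
            up[j] += h
            dn[j] -= h
            _, g_up = self._ll_and_score(up, self._Xs)
            _, g_dn = self._ll_and_score(dn, self._Xs)
            H[:, j] = (g_up - g_dn) / (2 * h)
        return 0.5 * (H + H.T)

    @staticmethod
    def _vcov_from_hessian(H) -> np.ndarray:
        neg_H = -H
        try:
            vcov = np.linalg.inv(neg_H)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(neg_H)
        # guard against tiny negative diagonals from differencing noise
        if np.any(np.diag(vcov) < 0):
            warnings.warn(
                "observed information not positive definite; using pseudo-inverse",
                stacklevel=2,
            )
            vcov = np.linalg.pinv(neg_H)
        return vcov


# ======================================================================
# results
# ======================================================================


class DLNMCountResults:
    """Fit results: estimates, uncertainty, diagnostics, effect summaries.

    Parameters are stored on the optimizer scale
    (``beta, log kappa, logit pi, log sigma_b``); convenience properties
    return the natural-scale values.  Confidence intervals for the
    auxiliary parameters are Wald intervals on the transformed scale mapped
    back through the link, which keeps them inside the parameter domain.
    """

    def __init__(self, model, params, llf, vcov, converged, optim_message, n_iter):
        self.model = model
        self.params = np.asarray(params, float)
        self.llf = llf
        self.vcov = vcov
        self.converged = converged
        self.optim_message = optim_message
        self.n_iter = n_iter
        self._fitted = None
        self._ranef = None

    # -- parameter access ----------------------------------------------
    @property
    def param_names(self):
        return self.model.param_names

    @property
    def beta(self) -> np.ndarray:
        return self.params[: self.model.n_fixed]

    @property
    def kappa(self) -> float | None:
        _, kappa, _, _ = self.model._unpack(self.params)
        return kappa

    @property
    def pi(self) -> float | None:
        _, _, pi, _ = self.model._unpack(self.params)
        return pi

    @property
    def sigma_b(self) -> float | None:
        _, _, _, sigma = self.model._unpack(self.params)
        return sigma

    @property
    def bse(self) -> np.ndarray:
        if self.vcov is None:
            raise ValueError("fit was run with compute_vcov=False")
        return np.sqrt(np.clip(np.diag(self.vcov), 0, None))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Wald CIs on the optimizer scale (transform aux entries yourself
        or use :meth:`conf_int_natural`)."""
        z = -special.ndtri(alpha / 2)
        se = self.bse
        return np.column_stack([self.params - z * se, self.params + z * se])

    def conf_int_natural(self, name: str, alpha: float = 0.05) -> tuple[float, float]:
        """Natural-scale CI for ``kappa``, ``pi``, ``sigma_b`` or a beta name.

        Wald intervals on the transformed (log / logit) scale mapped back
        through the link.  For ``sigma_b`` the critical value is Student-t
        with (number of groups - 1) degrees of freedom rather than normal:
        the random-intercept SD is informed by only as many effective
        observations as there are groups, and the normal quantile is known
        to undercover with few clusters.
        """
        trans = {
            "kappa": ("log_kappa", np.exp),
            "sigma_b": ("log_sigma_b", np.exp),
            "pi": ("logit_pi", special.expit),
        }
        if name in trans:
            pname, f = trans[name]
            idx = self.param_names.index(pname)
        else:
            idx = self.param_names.index(name)
            f = lambda v: v  # noqa: E731
        if name == "sigma_b":
            from scipy import stats

            df = max(len(self.model._slices) - 1, 1)
            crit = stats.t.ppf(1 - alpha / 2, df)
        else:
            crit = -special.ndtri(alpha / 2)
        se = self.bse[idx]
        est = self.params[idx]
        return float(f(est - crit * se)), float(f(est + crit * se))

    # -- information criteria ------------------------------------------
    @property
    def nobs(self) -> int:
        return self.model.y.size

    @property
    def df_model(self) -> int:
        return self.model.n_params

    @property
    def aic(self) -> float:
        return -2 * self.llf + 2 * self.df_model

    @property
    def bic(self) -> float:
        return -2 * self.llf + self.df_model * np.log(self.nobs)

    # -- fitted values and residuals ------------------------------------
    @property
    def random_effects(self) -> np.ndarray | None:
        """Conditional modes of the subregional intercepts (empirical Bayes)."""
        if not self.model.has_sigma:
            return None
        if self._ranef is None:
            beta, kappa, pi, sigma = self.model._unpack(self.params)
            eta0 = self.model.X @ beta + self.model.offset
            pi_eff = 0.0 if pi is None else pi
            modes = []
            for gi, sl in enumerate(self.model._slices):
                b, _ = self.model._find_mode(
                    self.model.y[sl], eta0[sl], kappa, pi_eff, sigma, gi
                )
                modes.append(b)
            self._ranef = np.array(modes)
        return self._ranef

    def _mu_conditional(self) -> np.ndarray:
        beta, _, _, _ = self.model._unpack(self.params)
        eta = self.model.X @ beta + self.model.offset
        if self.model.has_sigma:
            eta = eta + self.random_effects[self.model.groups]
        return np.exp(eta)

    @property
    def fittedvalues(self) -> np.ndarray:
        """Conditional expected counts ``(1 - pi) mu_it`` (mode-plug-in)."""
        if self._fitted is None:
            mu = self._mu_conditional()
            pi = self.pi or 0.0
            self._fitted = (1.0 - pi) * mu
        return self._fitted

    def resid(self, kind: str = "pearson") -> np.ndarray:
        """Raw, Pearson, or deviance residuals under the fitted family."""
        y = self.model.y
        mu = self._mu_conditional()
        kappa, pi = self.kappa, self.pi or 0.0
        mean = (1.0 - pi) * mu
        if kind == "raw":
            return y - mean
        if kind == "pearson":
            if kappa is None:
                var = (1.0 - pi) * mu * (1.0 + pi * mu)
            else:
                var = (1.0 - pi) * mu * (1.0 + mu / kappa + pi * mu)
            return (y - mean) / np.sqrt(var)
        if kind == "deviance":
            ll = loglik_parts(y, np.log(mu), kappa, pi)["logpmf"]
            ll_sat = self._saturated_loglik(y, kappa, pi)
            dev = 2.0 * np.clip(ll_sat - ll, 0.0, None)
            return np.sign(y - mean) * np.sqrt(dev)
        raise ValueError(f"unknown residual type {kind!r}")

    @staticmethod
    def _saturated_loglik(y, kappa, pi):
        """Per-observation log-lik maximized over mu (kappa, pi held fixed)."""
        y = np.asarray(y, float)
        out = np.zeros_like(y)
        pos = y > 0
        yp = y[pos]
        if kappa is None:
            base = yp * np.log(yp) - yp - special.gammaln(yp + 1.0)
        else:
            base = (
                special.gammaln(yp + kappa)
                - special.gammaln(kappa)
                - special.gammaln(yp + 1.0)
                + kappa * (np.log(kappa) - np.log(kappa + yp))
                + yp * (np.log(yp) - np.log(kappa + yp))
            )
        if pi:
            base = base + np.log1p(-pi)
        out[pos] = base
        # y = 0: sup over mu -> 0 gives probability pi + (1 - pi) = 1
        return out

    @property
    def deviance(self) -> float:
        return float(np.sum(self.resid("deviance") ** 2))

    @property
    def overdispersion_ratio(self) -> float:
        """Residual deviance over residual df for a Poisson fit.

        A ratio above 1 indicates extra-Poisson variability and motivates
        the negative binomial families.
        """
        if self.model.family != "poisson":
            raise ValueError("overdispersion ratio is defined for Poisson fits")
        return self.deviance / (self.nobs - self.model.n_fixed)

    @property
    def recommends_negbin(self) -> bool:
        return self.overdispersion_ratio > 1.0

    # -- cross-basis coefficient blocks ---------------------------------
    def crossbasis_block(self, exposure: str):
        """Coefficients and vcov sub-block of one exposure's cross-basis."""
        info = self.model.design_info
        if info is None or exposure not in info.cb_slices:
            raise KeyError(f"no cross-basis block for exposure {exposure!r}")
        sl = info.cb_slices[exposure]
        coefs = self.params[sl]
        vc = self.vcov[sl, sl] if self.vcov is not None else None
        return coefs, vc, info.cb_specs.get(exposure)

    # -- effect summaries (delegation) -----------------------------------
    def rr_surface(self, exposure: str, **kw):
        from . import effects

        return effects.rr_surface(self, exposure, **kw)

    def cumulative_irr(self, exposure: str, target: float, reference: float, **kw):
        from . import effects

        return effects.cumulative_irr(self, exposure, target, reference, **kw)

    def percentile_contrasts(self, exposure: str, **kw):
        from . import effects

        return effects.percentile_contrasts(self, exposure, **kw)

    # -- reporting -------------------------------------------------------
    def summary(self, alpha: float = 0.05, max_rows: int | None = 25) -> str:
        """Plain-text summary table in the statsmodels spirit."""
        lines = []
        fam = self.model.family.upper()
        re_txt = (
            f"random intercept ({len(self.model._slices)} groups)"
            if self.model.has_sigma
            else "no random effects"
        )
        lines.append(f"DLNM count model  family={fam}  {re_txt}")
        lines.append(
            f"nobs={self.nobs}  llf={self.llf:.3f}  AIC={self.aic:.3f}  "
            f"BIC={self.bic:.3f}  converged={self.converged}"
        )
        lines.append("-" * 72)
        lines.append(f"{'param':<24}{'estimate':>12}{'std err':>12}{'[%.1f%% CI]' % ((1-alpha)*100):>24}")
        ci = self.conf_int(alpha)
        se = self.bse
        rows = range(self.params.size)
        shown = list(rows)[:max_rows] if max_rows else list(rows)
        for j in shown:
            lines.append(
                f"{self.param_names[j]:<24}{self.params[j]:>12.4f}"
                f"{se[j]:>12.4f}{ci[j,0]:>12.4f}{ci[j,1]:>12.4f}"
            )
        if max_rows and self.params.size > max_rows:
            lines.append(f"... ({self.params.size - max_rows} more rows)")
        extras = []
        if self.kappa is not None:
            extras.append(f"kappa={self.kappa:.4f}")
        if self.pi is not None:
            extras.append(f"pi={self.pi:.4f}")
        if self.sigma_b is not None:
            extras.append(f"sigma_b={self.sigma_b:.4f}")
        if extras:
            lines.append("natural scale: " + "  ".join(extras))
        if self.sigma_b is not None and self.sigma_b < 1e-4:
            lines.append("note: sigma_b at/near the zero boundary")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serializable snapshot of the fit."""
        d = {
            "family": self.model.family,
            "param_names": self.param_names,
            "params": self.params.tolist(),
            "llf": self.llf,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "vcov": self.vcov.tolist() if self.vcov is not None else None,
        }
        info = self.model.design_info
        if info is not None and info.cb_specs:
            d["crossbasis_specs"] = {k: v.to_dict() for k, v in info.cb_specs.items()}
        return d
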