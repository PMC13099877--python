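"""Count-family log-densities and their derivatives.

All four response families used by the weekly hospitalization models live
here: Poisson (PO), negative binomial (NB), and their zero-inflated
counterparts (ZIP, ZINB).  The zero-inflated density is the two-part
mixture

    f(y) = pi * 1{y = 0} + (1 - pi) * f_base(y; mu, kappa),

with an intercept-only structural-zero probability ``pi``.  The negative
binomial is parameterized by its mean ``mu`` and dispersion ``kappa`` with
variance ``mu + mu^2 / kappa`` (Poisson is the ``kappa -> inf`` limit);
this single parameterization is used identically in simulation and
fitting.

Besides the log-pmfs, the module exposes the per-observation derivatives
with respect to the linear predictor ``eta = log mu``, ``log kappa`` and
``logit pi`` that the marginal-likelihood fitter needs.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = [
    "poisson_logpmf",
    "nb_logpmf",
    "zip_logpmf",
    "zinb_logpmf",
    "FAMILIES",
    "family_logpmf",
]

_MIN_PI = 0.0
_MAX_PI = 1.0 - 1e-12


def poisson_logpmf(y, mu):
    """Poisson log-pmf; ``mu > 0``."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    _check_mu(mu)
    return y * np.log(mu) - mu - special.gammaln(y + 1.0)


def nb_logpmf(y, mu, kappa):
    """Negative binomial log-pmf, mean/dispersion form (var = mu + mu^2/kappa)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    _check_mu(mu)
    if not np.all(np.asarray(kappa) > 0):
        raise ValueError("kappa must be > 0")
    return (
        special.gammaln(y + kappa)
        - special.gammaln(kappa)
        - special.gammaln(y + 1.0)
        + kappa * (np.log(kappa) - np.log(kappa + mu))
        + y * (np.log(mu) - np.log(kappa + mu))
    )


def _zi_logpmf(y, log_base, log_base0, pi):
    """Mixture log-pmf given base log-pmf and its value at y = 0."""
    pi = float(pi)
    if not (_MIN_PI <= pi < _MAX_PI):
        raise ValueError(f"pi must be in [0, 1), got {pi}")
    y = np.asarray(y)
    if pi == 0.0:
        return log_base
    with np.errstate(divide="ignore"):
        zero_part = np.logaddexp(np.log(pi), np.log1p(-pi) + log_base0)
    return np.where(y == 0, zero_part, np.log1p(-pi) + log_base)


def zip_logpmf(y, mu, pi):
    """Zero-inflated Poisson log-pmf; reduces exactly to Poisson at pi = 0."""
    lp = poisson_logpmf(y, mu)
    lp0 = -np.asarray(mu, dtype=float)
    return _zi_logpmf(y, lp, lp0, pi)


def zinb_logpmf(y, mu, kappa, pi):
    """Zero-inflated negative binomial log-pmf.

    ``log[pi 1{y=0} + (1 - pi) NB(y; mu, kappa)]`` computed in log space;
    at pi = 0 it equals the NB log-pmf for every y.
    """
    lp = nb_logpmf(y, mu, kappa)
    kappa = np.asarray(kappa, dtype=float)
    mu = np.asarray(mu, dtype=float)
    lp0 = kappa * (np.log(kappa) - np.log(kappa + mu))
    return _zi_logpmf(y, lp, lp0, pi)


def _check_mu(mu):
    if not np.all(mu > 0):
        raise ValueError("mu must be > 0")


# ----------------------------------------------------------------------
# derivative bundles used by the fitter
# ----------------------------------------------------------------------


def _base_parts(y, mu, kappa):
    """Log-pmf and eta/log-kappa derivatives of the base count family.

    Returns (logpmf, d_eta, d2_eta, d_logkappa) arrays; ``kappa=None``
    selects Poisson (the kappa derivative is then None).
    """
    if kappa is None:
        lp = poisson_logpmf(y, mu)
        d_eta = y - mu
        d2_eta = -mu
        return lp, d_eta, d2_eta, None
    lp = nb_logpmf(y, mu, kappa)
    denom = kappa + mu
    d_eta = y - (y + kappa) * mu / denom
    d2_eta = -(y + kappa) * kappa * mu / denom**2
    d_kappa = (
        special.digamma(y + kappa)
        - special.digamma(kappa)
        + np.log(kappa / denom)
        + 1.0
        - (y + kappa) / denom
    )
    return lp, d_eta, d2_eta, kappa * d_kappa  # chain rule to log-kappa


def family_logpmf(y, mu, kappa=None, pi=0.0):
    """Log-pmf of any of the four families (kappa None => Poisson kernel)."""
    if pi == 0.0:
        return _base_parts(y, mu, kappa)[0]
    if kappa is None:
        return zip_logpmf(y, mu, pi)
    return zinb_logpmf(y, mu, kappa, pi)


def loglik_parts(y, eta, kappa=None, pi=0.0):
    """Per-observation log-pmf and derivatives for the fitter.

    Parameters are on the fitting scales: ``eta = log mu`` enters via the
    design, ``kappa`` and ``pi`` are the natural-scale dispersion and
    structural-zero probability (derivatives returned w.r.t. ``log kappa``
    and ``logit pi``).

    Returns
    -------
    dict with keys ``logpmf``, ``d_eta``, ``d2_eta``, ``d_logkappa``,
    ``d_logitpi`` (the latter two None when the parameter is absent).
    """
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    mu = np.exp(np.clip(eta, -500.0, 50.0))
    lp, d_eta, d2_eta, d_lk = _base_parts(y, mu, kappa)

    if pi == 0.0:
        return {
            "logpmf": lp,
            "d_eta": d_eta,
            "d2_eta": d2_eta,
            "d_logkappa": d_lk,
            "d_logitpi": None,
        }

    is0 = y == 0
    if kappa is None:
        lp0 = -mu
        d0 = -mu  # d lp0 / d eta
        d0p = -mu  # second derivative
        d_lk0 = None
    else:
        denom = kappa + mu
        lp0 = kappa * (np.log(kappa) - np.log(denom))
        d0 = -kappa * mu / denom
        d0p = -(kappa**2) * mu / denom**2
        d_lk0 = kappa * (np.log(kappa / denom) + 1.0 - kappa / denom)

    log_pi = np.log(pi)
    log1m = np.log1p(-pi)
    zero_lp = np.logaddexp(log_pi, log1m + lp0)
    # u = (1-pi) f0 / [pi + (1-pi) f0]: posterior weight of the count kernel
    u = np.exp(log1m + lp0 - zero_lp)

    logpmf = np.where(is0, zero_lp, log1m + lp)
    d_eta_out = np.where(is0, u * d0, d_eta)
    d2_eta_out = np.where(is0, u * (1.0 - u) * d0**2 + u * d0p, d2_eta)
    if d_lk is not None:
        d_lk_out = np.where(is0, u * d_lk0, d_lk)
    else:
        d_lk_out = None
    # logit-pi derivative: d pi / d theta = pi (1 - pi);
    # at y = 0, d zero_lp / d pi = (1 - f0)/P0 which simplifies via u
    d_theta = np.where(is0, 1.0 - pi - u, -pi)
    return {
        "logpmf": logpmf,
        "d_eta": d_eta_out,
        "d2_eta": d2_eta_out,
        "d_logkappa": d_lk_out,
        "d_logitpi": d_theta,
    }


#: canonical family codes and which auxiliary parameters they carry
FAMILIES = {
    "poisson": {"kappa": False, "pi": False},
    "negbin": {"kappa": True, "pi": False},
    "zip": {"kappa": False, "pi": True},
    "zinb": {"kappa": True, "pi": True},
}
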