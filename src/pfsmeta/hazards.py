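"""Parametric hazard families and the survival transform.

Four hazard families are supported, each giving the instantaneous event
rate h(t) (per month) for progression-free survival:

* ``exponential``   : h(t) = lambda0
* ``gompertz``      : h(t) = lambda0 * exp(beta * t)
* ``weibull_form``  : h(t) = lambda0 * exp(beta * ln t) = lambda0 * t**beta
                      (a Weibull hazard with shape beta + 1, kept in this
                      log-time regression form rather than the usual
                      shape/scale parameterization)
* ``lognormal``     : h(t) = pdf/(1 - cdf) of a log-normal with log-time
                      location mu and scale sigma

Survival is S(t) = exp(-integral_0^t h(u) du); closed forms are used for
every family, with the Gompertz beta -> 0 removable singularity handled by
a series branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import log_ndtr, ndtr

__all__ = [
    "FAMILIES",
    "HazardParams",
    "hazard",
    "survival",
    "median_survival_time",
]

FAMILIES = ("exponential", "gompertz", "weibull_form", "lognormal")

# below this |beta| the Gompertz cumulative hazard uses its Taylor series
_GOMPERTZ_SERIES_CUT = 1e-8

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class HazardParams:
    """Parameters of one hazard family.

    Only the fields relevant to ``family`` are used: ``lambda0`` (and
    ``beta`` except for exponential) for the first three families, ``mu``
    and ``sigma`` (log-time location/scale) for the log-normal.
    """

    family: str
    lambda0: float | None = None
    beta: float | None = None
    mu: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown hazard family: {self.family!r}")
        if self.family == "lognormal":
            if self.mu is None or self.sigma is None:
                raise ValueError("lognormal requires mu and sigma")
            if self.sigma <= 0:
                raise ValueError("sigma must be > 0")
        else:
            if self.lambda0 is None:
                raise ValueError(f"{self.family} requires lambda0")
            if self.lambda0 <= 0:
                raise ValueError("lambda0 must be > 0")
            if self.family == "exponential":
                pass
            elif self.beta is None:
                raise ValueError(f"{self.family} requires beta")
            elif self.family == "weibull_form" and self.beta <= -1:
                raise ValueError("weibull_form requires beta > -1")


def hazard(params: HazardParams, t):
    """Instantaneous hazard rate (1/month) at time ``t`` (> 0).

    Accepts a scalar or array of times; vectorized over ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("hazard requires t > 0")
    f = params.family
    if f == "exponential":
        return np.broadcast_to(params.lambda0, t.shape).copy() if t.shape else float(params.lambda0)
    if f == "gompertz":
        out = params.lambda0 * np.exp(params.beta * t)
    elif f == "weibull_form":
        out = params.lambda0 * np.power(t, params.beta)
    else:  # lognormal: phi(z) / (sigma * t * Phi(-z)), complementary form
        z = (np.log(t) - params.mu) / params.sigma
        log_pdf = -0.5 * z * z - _LOG_SQRT_2PI - np.log(params.sigma * t)
        out = np.exp(log_pdf - log_ndtr(-z))
    return out if out.shape else float(out)


def _cumulative_hazard(params: HazardParams, t: np.ndarray) -> np.ndarray:
    f = params.family
    if f == "exponential":
        return params.lambda0 * t
    if f == "gompertz":
        b = params.beta
        if abs(b) < _GOMPERTZ_SERIES_CUT:
            bt = b * t
            return params.lambda0 * t * (1.0 + bt / 2.0 + bt * bt / 6.0)
        return params.lambda0 * (np.exp(b * t) - 1.0) / b
    if f == "weibull_form":
        k = params.beta + 1.0
        with np.errstate(divide="ignore"):
            return np.where(t > 0, params.lambda0 * np.power(t, k) / k, 0.0)
    raise AssertionError(f)


def survival(params: HazardParams, t):
    """Survival probability S(t) = exp(-H(t)); S(0) = 1 for every family."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival requires t >= 0")
    if params.family == "lognormal":
        with np.errstate(divide="ignore"):
            z = np.where(t > 0, (np.log(np.where(t > 0, t, 1.0)) - params.mu) / params.sigma, -np.inf)
        out = ndtr(-z)
    else:
        out = np.exp(-_cumulative_hazard(params, t))
    return out if out.shape else float(out)


def median_survival_time(params: HazardParams) -> float:
    """The time t (months) at which S(t) = 0.5.

    Closed forms are used where they exist; otherwise a bracketed root
    search on S(t) - 0.5 to |S - 0.5| <= 1e-10.  A Gompertz hazard with
    beta < 0 has finite total cumulative hazard lambda0/|beta|; if that
    plateau is below ln 2 the survival curve never reaches one half and a
    ValueError is raised.
    """
    f = params.family
    ln2 = math.log(2.0)
    if f == "lognormal":
        return math.exp(params.mu)
    if f == "exponential":
        return ln2 / params.lambda0
    if f == "weibull_form":
        k = params.beta + 1.0
        return (k * ln2 / params.lambda0) ** (1.0 / k)
    # gompertz
    b = params.beta
    if abs(b) < _GOMPERTZ_SERIES_CUT:
        return ln2 / params.lambda0
    arg = 1.0 + b * ln2 / params.lambda0
    if arg <= 0:
        raise ValueError("gompertz survival never falls to 0.5 (hazard decays too fast)")
    t0 = math.log(arg) / b
    # polish with a bracketed root search to the stated tolerance
    lo, hi = 0.5 * t0, 2.0 * t0 + 1e-12
    g = lambda t: float(survival(params, t)) - 0.5
    if g(lo) * g(hi) > 0:
        return t0
    return brentq(g, lo, hi, xtol=1e-12, rtol=8.9e-16)
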