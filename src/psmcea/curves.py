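"""Parametric survival curves used for extrapolating trial endpoints.

Six families are supported: exponential, Weibull, log-logistic, lognormal,
Gompertz and generalized gamma (Prentice location-scale-shape form, which
contains the lognormal as the interior ``Q -> 0`` limit).  Each curve knows
its survival function, hazard, log-density and quantile function, so the
same object serves maximum-likelihood fitting, cohort simulation and the
partitioned-survival engine.

Curves carry an explicit time unit tag (``days`` by default); the model
mixes 21-day cycles, month-denominated medians and year-denominated
horizons, so conversions are centralised here (1 month = 30.4375 days,
1 year = 365.25 days).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import special as sc

__all__ = [
    "FAMILIES",
    "N_PARAMS",
    "DAYS_PER_MONTH",
    "DAYS_PER_YEAR",
    "ParametricCurve",
    "survival_at",
    "curve_from_median",
]

FAMILIES = (
    "exponential",
    "weibull",
    "loglogistic",
    "lognormal",
    "gompertz",
    "generalized_gamma",
)

#: free parameters per family
N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "loglogistic": 2,
    "lognormal": 2,
    "gompertz": 2,
    "generalized_gamma": 3,
}

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25

_UNIT_DAYS = {"days": 1.0, "months": DAYS_PER_MONTH, "years": DAYS_PER_YEAR}

# below this |Q| the generalized gamma is evaluated as its lognormal limit
_GG_LOGNORMAL_EPS = 1e-5


class ParameterError(ValueError):
    """Raised when a parameter vector violates its family's constraints."""


def _validate(family: str, params: tuple[float, ...]) -> None:
    if family not in FAMILIES:
        raise ParameterError(f"unknown family {family!r}; expected one of {FAMILIES}")
    if len(params) != N_PARAMS[family]:
        raise ParameterError(
            f"{family} takes {N_PARAMS[family]} parameters, got {len(params)}"
        )
    p = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ParameterError(f"{family} parameters must be finite, got {params}")
    if family == "exponential" and p[0] <= 0:
        raise ParameterError(f"exponential rate must be positive, got {p[0]}")
    if family in ("weibull", "loglogistic") and (p[0] <= 0 or p[1] <= 0):
        raise ParameterError(f"{family} shape and scale must be positive, got {params}")
    if family == "lognormal" and p[1] <= 0:
        raise ParameterError(f"lognormal sigma must be positive, got {p[1]}")
    if family == "gompertz" and p[1] <= 0:
        raise ParameterError(f"gompertz rate must be positive, got {p[1]}")
    if family == "generalized_gamma" and p[1] <= 0:
        raise ParameterError(f"generalized_gamma sigma must be positive, got {p[1]}")


@dataclass(frozen=True)
class ParametricCurve:
    """A named survival family with a fixed parameter vector.

    Parameters per family (in the curve's own time unit):

    - ``exponential``: (rate,) with S(t) = exp(-rate * t)
    - ``weibull``: (shape a, scale b) with S(t) = exp(-(t/b)^a)
    - ``loglogistic``: (shape a, scale b) with S(t) = 1 / (1 + (t/b)^a)
    - ``lognormal``: (mu, sigma) with S(t) = 1 - Phi((ln t - mu)/sigma)
    - ``gompertz``: (shape a, rate b) with S(t) = exp(-(b/a)(e^{a t} - 1))
    - ``generalized_gamma``: (mu, sigma, Q), Prentice form; Q -> 0 is the
      lognormal(mu, sigma) limit.
    """

    family: str
    params: tuple[float, ...]
    time_unit: str = "days"

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        _validate(self.family, self.params)
        if self.time_unit not in _UNIT_DAYS:
            raise ParameterError(
                f"time_unit must be one of {tuple(_UNIT_DAYS)}, got {self.time_unit!r}"
            )

    # -- evaluation ---------------------------------------------------------

    def survival(self, t):
        """S(t); ``t`` in the curve's time unit, scalar or array, t >= 0."""
        t, scalar = _as_time_array(t)
        out = np.exp(self.log_survival(t))
        return float(out[0]) if scalar else out

    def log_survival(self, t):
        t, scalar = _as_time_array(t)
        out = _log_survival(self.family, self.params, t)
        return float(out[0]) if scalar else out

    def log_density(self, t):
        """log f(t) for event contributions to a censored likelihood."""
        t, scalar = _as_time_array(t)
        out = _log_density(self.family, self.params, t)
        return float(out[0]) if scalar else out

    def hazard(self, t):
        t, scalar = _as_time_array(t)
        with np.errstate(over="ignore"):
            out = np.exp(
                _log_density(self.family, self.params, t)
                - _log_survival(self.family, self.params, t)
            )
        return float(out[0]) if scalar else out

    def quantile(self, p):
        """Inverse CDF: the time t with 1 - S(t) = p."""
        p_arr = np.atleast_1d(np.asarray(p, dtype=float))
        if np.any((p_arr < 0) | (p_arr >= 1)):
            raise ValueError("quantile probabilities must lie in [0, 1)")
        out = _quantile(self.family, self.params, p_arr)
        return float(out[0]) if np.isscalar(p) or np.ndim(p) == 0 else out

    def median(self) -> float:
        return float(self.quantile(0.5))

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` event times by inverse-transform sampling."""
        return _quantile(self.family, self.params, rng.uniform(size=int(n)))

    # -- unit bookkeeping ---------------------------------------------------

    def to_unit(self, unit: str) -> "ParametricCurve":
        """Re-express the parameter vector in another time unit."""
        if unit not in _UNIT_DAYS:
            raise ParameterError(f"unknown time unit {unit!r}")
        if unit == self.time_unit:
            return self
        r = _UNIT_DAYS[self.time_unit] / _UNIT_DAYS[unit]
        p = self.params
        if self.family == "exponential":
            new = (p[0] / r,)
        elif self.family in ("weibull", "loglogistic"):
            new = (p[0], p[1] * r)
        elif self.family == "lognormal":
            new = (p[0] + np.log(r), p[1])
        elif self.family == "gompertz":
            new = (p[0] / r, p[1] / r)
        else:  # generalized_gamma
            new = (p[0] + np.log(r), p[1], p[2])
        return ParametricCurve(self.family, new, time_unit=unit)

    def __call__(self, t):
        return self.survival(t)


def _as_time_array(t):
    scalar = np.isscalar(t) or np.ndim(t) == 0
    arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(arr < 0) or np.any(~np.isfinite(arr)):
        raise ValueError("times must be finite and non-negative")
    return arr, scalar


# -- family formulas (vectorised over t) -----------------------------------


def _log_survival(family: str, params: tuple[float, ...], t: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        if family == "exponential":
            return -params[0] * t
        if family == "weibull":
            a, b = params
            return -((t / b) ** a)
        if family == "loglogistic":
            a, b = params
            return -np.log1p((t / b) ** a)
        if family == "lognormal":
            return _lognormal_logsf(t, params[0], params[1])
        if family == "gompertz":
            a, b = params
            if abs(a) < 1e-12:
                return -b * t
            return -(b / a) * np.expm1(a * t)
        # generalized gamma
        mu, sigma, q = params
        if abs(q) < _GG_LOGNORMAL_EPS:
            return _lognormal_logsf(t, mu, sigma)
        gamma = q**-2
        y = (np.log(t) - mu) / sigma
        u = gamma * np.exp(q * y)
        if q > 0:
            val = np.log(sc.gammaincc(gamma, u))
        else:
            val = np.log(sc.gammainc(gamma, u))
        # t == 0 is survival 1 regardless of branch direction
        return np.where(t == 0.0, 0.0, val)


def _lognormal_logsf(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    out = np.full_like(t, 0.0)
    pos = t > 0
    z = (np.log(t[pos]) - mu) / sigma
    out[pos] = sc.log_ndtr(-z)
    return out


def _log_density(family: str, params: tuple[float, ...], t: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        if family == "exponential":
            lam = params[0]
            return np.log(lam) - lam * t
        if family == "weibull":
            a, b = params
            z = t / b
            return np.log(a / b) + (a - 1) * np.log(z) - z**a
        if family == "loglogistic":
            a, b = params
            z = t / b
            return np.log(a / b) + (a - 1) * np.log(z) - 2 * np.log1p(z**a)
        if family == "lognormal":
            return _lognormal_logpdf(t, params[0], params[1])
        if family == "gompertz":
            a, b = params
            if abs(a) < 1e-12:
                return np.log(b) - b * t
            return np.log(b) + a * t - (b / a) * np.expm1(a * t)
        mu, sigma, q = params
        if abs(q) < _GG_LOGNORMAL_EPS:
            return _lognormal_logpdf(t, mu, sigma)
        gamma = q**-2
        y = (np.log(t) - mu) / sigma
        return (
            np.log(abs(q))
            - np.log(sigma * t)
            + gamma * np.log(gamma)
            + gamma * (q * y - np.exp(q * y))
            - sc.gammaln(gamma)
        )


def _lognormal_logpdf(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    out = np.full_like(t, -np.inf)
    pos = t > 0
    z = (np.log(t[pos]) - mu) / sigma
    out[pos] = -0.5 * z**2 - 0.5 * np.log(2 * np.pi) - np.log(sigma * t[pos])
    return out


def _quantile(family: str, params: tuple[float, ...], p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        if family == "exponential":
            return -np.log1p(-p) / params[0]
        if family == "weibull":
            a, b = params
            return b * (-np.log1p(-p)) ** (1.0 / a)
        if family == "loglogistic":
            a, b = params
            return b * (p / (1.0 - p)) ** (1.0 / a)
        if family == "lognormal":
            return _lognormal_ppf(p, params[0], params[1])
        if family == "gompertz":
            a, b = params
            if abs(a) < 1e-12:
                return -np.log1p(-p) / b
            arg = 1.0 - (a / b) * np.log1p(-p)
            if np.any(arg <= 0):
                raise ValueError(
                    "gompertz with negative shape plateaus above the requested quantile"
                )
            return np.log(arg) / a
        mu, sigma, q = params
        if abs(q) < _GG_LOGNORMAL_EPS:
            return _lognormal_ppf(p, mu, sigma)
        gamma = q**-2
        if q > 0:
            u = sc.gammaincinv(gamma, p)
        else:
            u = sc.gammaincinv(gamma, 1.0 - p)
        return np.exp(mu + (sigma / q) * np.log(u / gamma))


def _lognormal_ppf(p: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = np.exp(mu + sigma * sc.ndtri(p[pos]))
    return out


# -- public helpers ---------------------------------------------------------


def survival_at(curve: ParametricCurve, t) -> float | np.ndarray:
    """Survival fraction S(t); ``t`` in the curve's time unit, t >= 0."""
    return curve.survival(t)


def curve_from_median(
    family: str, median: float, extra: float | None = None, time_unit: str = "months"
) -> ParametricCurve:
    """Calibrate a curve from a published median survival time.

    Supported calibrations: ``exponential`` (rate = ln 2 / median) and
    ``lognormal`` (mu = ln median, sigma = ``extra``).  Either way
    S(median) = 0.5 exactly, which is the only constraint a published
    median imposes.
    """
    if median <= 0 or not np.isfinite(median):
        raise ValueError(f"median must be positive and finite, got {median}")
    if family == "exponential":
        return ParametricCurve("exponential", (np.log(2.0) / median,), time_unit)
    if family == "lognormal":
        if extra is None or extra <= 0:
            raise ValueError("lognormal calibration needs a positive sigma as `extra`")
        return ParametricCurve("lognormal", (np.log(median), float(extra)), time_unit)
    raise ValueError(
        f"median calibration supports exponential and lognormal, not {family!r}"
    )
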