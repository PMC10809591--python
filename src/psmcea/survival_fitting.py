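"""Parametric survival fitting, model selection and pseudo-IPD reconstruction.

The extrapolation step of a partitioned-survival analysis fits several
parametric families to each trial endpoint by maximum likelihood under
right-censoring (log-likelihood = sum over events of log f(t) plus sum over
censored records of log S(t)) and picks a family by AIC or BIC.  When only
a digitized Kaplan-Meier figure is available, pseudo individual patient
data are first reconstructed from the curve coordinates (Guyot-style:
events are allocated from survival drops, censorings from numbers-at-risk
discrepancies; without a risk table, censoring is assumed to occur only at
the end of follow-up).  When only a published median is available, a curve
is calibrated directly (`curve_from_median`).

Optimisation is multi-start quasi-Newton (L-BFGS-B) on transformed
parameters (log for positive-constrained ones), 3 starts, tolerance 1e-8
on the log-likelihood; ties in model selection break toward the family
with fewer parameters, then lexicographic family name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .curves import (
    FAMILIES,
    N_PARAMS,
    ParametricCurve,
    curve_from_median,
    survival_at,
)
from .synthetic_ipd import IPDataset, KMDigitized

__all__ = [
    "FitResult",
    "fit_parametric",
    "fit_all_families",
    "select_model",
    "criterion_table",
    "reconstruct_ipd_from_km",
    "curve_from_median",
    "survival_at",
]


@dataclass(frozen=True)
class FitResult:
    """One family's maximum-likelihood fit with its information criteria."""

    curve: ParametricCurve
    loglik: float
    k: int
    n: int
    aic: float
    bic: float
    converged: bool

    @classmethod
    def from_loglik(
        cls, curve: ParametricCurve, loglik: float, n: int, converged: bool
    ) -> "FitResult":
        k = N_PARAMS[curve.family]
        return cls(
            curve=curve,
            loglik=loglik,
            k=k,
            n=n,
            aic=2 * k - 2 * loglik,
            bic=k * np.log(n) - 2 * loglik,
            converged=bool(converged and np.isfinite(loglik)),
        )


# -- parameter transforms: optimizer space <-> natural space ----------------

# which coordinates are log-transformed (positivity constrained)
_LOG_MASK = {
    "exponential": (True,),
    "weibull": (True, True),
    "loglogistic": (True, True),
    "lognormal": (False, True),
    "gompertz": (False, True),
    "generalized_gamma": (False, True, False),
}


def _to_natural(family: str, theta: np.ndarray) -> tuple[float, ...]:
    mask = _LOG_MASK[family]
    return tuple(np.exp(v) if m else v for v, m in zip(theta, mask))


def _to_theta(family: str, params) -> np.ndarray:
    mask = _LOG_MASK[family]
    return np.array([np.log(v) if m else v for v, m in zip(params, mask)])


def _initial_params(family: str, times: np.ndarray, events: np.ndarray) -> list:
    """Moment-based starting points; first entry is the primary start."""
    ev_times = times[events == 1]
    rate0 = max(events.sum() / times.sum(), 1e-10)
    logs = np.log(ev_times)
    m, s = float(np.mean(logs)), float(np.std(logs))
    s = max(s, 0.05)
    med = float(np.median(ev_times))
    if family == "exponential":
        return [(rate0,)]
    if family == "weibull":
        return [(1.2 / s, np.exp(m + 0.5772 * s)), (1.0, 1.0 / rate0)]
    if family == "loglogistic":
        return [(np.pi / (s * np.sqrt(3.0)), med), (1.0, med)]
    if family == "lognormal":
        return [(m, s)]
    if family == "gompertz":
        return [(1e-4, rate0), (1e-3, rate0)]
    # generalized gamma: bracket the lognormal limit from both sides
    return [(m, s, 0.5), (m, s, -0.5), (m, s, 1.5)]


def fit_parametric(data: IPDataset, family: str, n_starts: int = 3) -> FitResult:
    """Maximum-likelihood fit of one family to right-censored records.

    Returns a flagged (``converged=False``) result rather than raising when
    the optimizer fails; a dataset with no events is an error because the
    likelihood is then unbounded in the scale.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    times, events = data.times, data.events
    n = len(times)
    if events.sum() == 0:
        raise ValueError("cannot fit a survival model to data with no events")

    ev, ce = times[events == 1], times[events == 0]

    def nll(theta: np.ndarray) -> float:
        try:
            curve = ParametricCurve(family, _to_natural(family, theta))
        except ValueError:
            return np.inf
        with np.errstate(all="ignore"):
            ll = float(np.sum(curve.log_density(ev)))
            if len(ce):
                ll += float(np.sum(curve.log_survival(ce)))
        return np.inf if not np.isfinite(ll) else -ll

    starts = [_to_theta(family, p) for p in _initial_params(family, times, events)]
    jitter_rng = np.random.default_rng(0)
    while len(starts) < n_starts:
        starts.append(starts[0] + jitter_rng.normal(scale=0.3, size=len(starts[0])))
    starts = starts[:n_starts]

    best, best_val, any_success = None, np.inf, False
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B", options={"ftol": 1e-8, "gtol": 1e-8})
        if np.isfinite(res.fun) and res.fun < best_val:
            best, best_val = res, res.fun
            any_success = any_success or res.success
        elif res.success and np.isfinite(res.fun):
            any_success = True

    if best is None:
        # optimizer never found a finite likelihood; report the primary start
        curve = ParametricCurve(family, _to_natural(family, starts[0]))
        return FitResult.from_loglik(curve, -np.inf, n, converged=False)
    curve = ParametricCurve(family, _to_natural(family, best.x))
    return FitResult.from_loglik(curve, -best_val, n, converged=any_success)


def fit_all_families(data: IPDataset, families=FAMILIES) -> list[FitResult]:
    return [fit_parametric(data, fam) for fam in families]


def select_model(fits: list[FitResult], criterion: str = "AIC") -> FitResult:
    """Pick the converged fit minimizing AIC or BIC.

    Ties (within 1e-9) go to the family with fewer parameters, then to the
    lexicographically first family name, so selection is reproducible.
    """
    crit = criterion.lower()
    if crit not in ("aic", "bic"):
        raise ValueError(f"criterion must be 'AIC' or 'BIC', got {criterion!r}")
    ok = [f for f in fits if f.converged]
    if not ok:
        raise ValueError("no converged fits to select among")
    return min(ok, key=lambda f: (round(getattr(f, crit), 9), f.k, f.curve.family))


def criterion_table(fits: list[FitResult]) -> pd.DataFrame:
    """AIC/BIC comparison table across candidate families."""
    return pd.DataFrame(
        {
            "family": [f.curve.family for f in fits],
            "loglik": [f.loglik for f in fits],
            "k": [f.k for f in fits],
            "aic": [f.aic for f in fits],
            "bic": [f.bic for f in fits],
            "converged": [f.converged for f in fits],
        }
    )


def reconstruct_ipd_from_km(
    curve: KMDigitized,
    n_initial: int | None = None,
    arm: str = "arm",
    endpoint: str = "OS",
) -> IPDataset:
    """Rebuild pseudo individual patient data from digitized KM coordinates.

    Interval-wise allocation: at each digitized drop the number of events is
    the one whose product-limit step best matches the printed survival given
    the current at-risk count.  With a numbers-at-risk table, censorings are
    inserted at each risk-table boundary to reconcile the at-risk count;
    without one, all remaining subjects are censored at the curve's end.

    ``n_initial`` (default: first risk-table count, else 100) sets the
    cohort size and hence the resolution of the reconstruction.
    """
    if n_initial is None:
        n_initial = int(curve.n_risk[0]) if curve.n_risk is not None else 100
    if n_initial < 1:
        raise ValueError("n_initial must be at least 1")
    if float(curve.survival.min()) >= 1.0 - 1e-12:
        raise ValueError("flat survival curve at 1.0: no events to place")

    boundaries: list[tuple[float, int]] = []
    if curve.n_risk is not None:
        boundaries = [
            (float(t), int(r))
            for t, r in zip(curve.risk_times, curve.n_risk)
            if float(t) > 0.0
        ]

    times: list[float] = []
    events: list[int] = []
    at_risk = int(n_initial)
    s_hat = 1.0
    b_idx = 0

    for t, s in zip(curve.times, curve.survival):
        if t == 0.0:
            continue
        # reconcile at-risk counts at any risk-table boundary passed
        while b_idx < len(boundaries) and boundaries[b_idx][0] < t:
            bt, target = boundaries[b_idx]
            n_cens = at_risk - target
            if n_cens > 0:
                times.extend([bt] * n_cens)
                events.extend([0] * n_cens)
                at_risk = target
            b_idx += 1
        if at_risk == 0:
            break
        drop = 1.0 - s / s_hat if s_hat > 0 else 0.0
        d = int(round(at_risk * max(drop, 0.0)))
        d = min(max(d, 0), at_risk)
        if d > 0:
            times.extend([float(t)] * d)
            events.extend([1] * d)
            s_hat *= 1.0 - d / at_risk
            at_risk -= d

    if at_risk > 0:  # administrative censoring at end of follow-up
        times.extend([float(curve.times[-1])] * at_risk)
        events.extend([0] * at_risk)

    frame = pd.DataFrame({"time_days": times, "event": events, "arm": arm})
    return IPDataset(frame, endpoint)
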