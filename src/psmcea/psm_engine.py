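"""Partitioned-survival engine: curves in, per-cycle state occupancy out.

A three-state partitioned survival model (progression-free, progressed,
dead) reads state membership directly off the overlaid OS and PFS curves
each cycle: PFS membership is S_pfs, dead is 1 - S_os, progressed is the
remainder.  Because the two curves are fitted independently they can cross;
memberships are clamped (PFS <= OS) and the crossed range is reported as a
warning.

Half-cycle correction is implemented as midpoint evaluation: memberships
and discount factors are taken at t_k = (k - 1/2) * cycle_length rather
than at cycle boundaries.  General-population mortality can be blended in
as a hazard floor on the OS curve, so extrapolated disease survival never
beats the background population.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .curves import DAYS_PER_YEAR, ParametricCurve

__all__ = [
    "CyclePlan",
    "build_cycle_plan",
    "LifeTable",
    "synthetic_life_table",
    "BlendedSurvival",
    "apply_background_mortality",
    "Trace",
    "partition_memberships",
    "on_treatment_occupancy",
    "export_trace",
]


@dataclass(frozen=True)
class CyclePlan:
    """Discrete cycle grid with discounting and evaluation convention.

    Defaults follow the base case: 21-day cycles over a 5-year horizon
    (ceil(5 * 365.25 / 21) = 87 cycles), 5% annual discount, midpoint
    evaluation (half-cycle correction).
    """

    cycle_length_days: float = 21.0
    horizon_years: float = 5.0
    annual_discount: float = 0.05
    evaluation: str = "midpoint"
    n_cycles: int = field(init=False)

    def __post_init__(self) -> None:
        if self.cycle_length_days <= 0 or self.horizon_years <= 0:
            raise ValueError("cycle length and horizon must be positive")
        if self.annual_discount < 0:
            raise ValueError("discount rate cannot be negative")
        if self.evaluation not in ("midpoint", "boundary"):
            raise ValueError("evaluation must be 'midpoint' or 'boundary'")
        n = math.ceil(self.horizon_years * DAYS_PER_YEAR / self.cycle_length_days)
        object.__setattr__(self, "n_cycles", int(n))

    @property
    def eval_times_days(self) -> np.ndarray:
        """Evaluation time of each cycle k = 1..n_cycles, in days."""
        k = np.arange(1, self.n_cycles + 1, dtype=float)
        offset = 0.5 if self.evaluation == "midpoint" else 0.0
        return (k - offset) * self.cycle_length_days

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR

    def discount_factors(self) -> np.ndarray:
        return (1.0 + self.annual_discount) ** (-self.eval_times_days / DAYS_PER_YEAR)

    def with_discount(self, annual_discount: float) -> "CyclePlan":
        return replace(self, annual_discount=annual_discount)


def build_cycle_plan(
    horizon_years: float = 5.0,
    cycle_length_days: float = 21.0,
    discount: float = 0.05,
    evaluation: str = "midpoint",
) -> CyclePlan:
    return CyclePlan(
        cycle_length_days=cycle_length_days,
        horizon_years=horizon_years,
        annual_discount=discount,
        evaluation=evaluation,
    )


@dataclass(frozen=True)
class LifeTable:
    """General-population annual death probabilities q(age)."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.ages, dtype=float)
        q = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", a)
        object.__setattr__(self, "qx", q)
        if a.shape != q.shape or a.ndim != 1 or len(a) == 0:
            raise ValueError("ages and qx must be equal-length 1-d arrays")
        if np.any(np.diff(a) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any((q < 0) | (q > 1)):
            raise ValueError("annual death probabilities must lie in [0, 1]")

    def hazard_per_day(self, age_years) -> np.ndarray:
        """Piecewise-constant daily hazard -ln(1 - q)/365.25 at given ages."""
        age = np.atleast_1d(np.asarray(age_years, dtype=float))
        if np.any(age > self.ages[-1]):
            warnings.warn(
                f"ages beyond the life table ({self.ages[-1]:.0f}y) use the last row",
                stacklevel=2,
            )
        idx = np.clip(np.searchsorted(self.ages, age, side="right") - 1, 0, len(self.ages) - 1)
        q = np.clip(self.qx[idx], 0.0, 1.0 - 1e-12)
        return -np.log1p(-q) / DAYS_PER_YEAR

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(df["age"].to_numpy(), df["qx"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "qx": self.qx}).to_csv(path, index=False)


def synthetic_life_table(max_age: int = 100) -> LifeTable:
    """Synthetic all-cause life table (Gompertz-Makeham shape).

    Stands in for a national resident-population mortality table, which is
    not shipped: q(age) = 1 - exp(-(A + B e^{c*age})) with A = 5e-4,
    B = 3e-5, c = 0.085, giving roughly 0.3% annual mortality at age 50
    rising to ~3% at age 80.
    """
    ages = np.arange(0, max_age + 1, dtype=float)
    hazard = 5e-4 + 3e-5 * np.exp(0.085 * ages)
    return LifeTable(ages, 1.0 - np.exp(-hazard))


class BlendedSurvival:
    """OS curve with a general-population hazard floor.

    The adjusted hazard is max(h_model(t), h_background(start_age + t)) and
    the adjusted survival exp(-integral of the adjusted hazard), evaluated
    by daily trapezoid integration.  The result never exceeds the model OS
    curve.
    """

    def __init__(
        self,
        os_curve: ParametricCurve,
        life_table: LifeTable,
        start_age_years: float = 50.0,
        grid_step_days: float = 1.0,
    ):
        if start_age_years < life_table.ages[0]:
            raise ValueError("start age below the life table's range")
        self.os_curve = os_curve.to_unit("days")
        self.life_table = life_table
        self.start_age_years = float(start_age_years)
        self.grid_step_days = float(grid_step_days)
        self._grid: np.ndarray | None = None
        self._cumhaz: np.ndarray | None = None

    def _ensure_grid(self, t_max: float) -> None:
        if self._grid is not None and self._grid[-1] >= t_max:
            return
        grid = np.arange(0.0, t_max + 2 * self.grid_step_days, self.grid_step_days)
        h_model = self.os_curve.hazard(grid)
        h_model = np.nan_to_num(h_model, nan=0.0, posinf=1e6)
        ages = self.start_age_years + grid / DAYS_PER_YEAR
        h_bg = self.life_table.hazard_per_day(ages)
        h = np.maximum(h_model, h_bg)
        cumhaz = np.concatenate(
            [[0.0], np.cumsum(0.5 * (h[1:] + h[:-1]) * np.diff(grid))]
        )
        self._grid, self._cumhaz = grid, cumhaz

    def __call__(self, t):
        scalar = np.isscalar(t) or np.ndim(t) == 0
        arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(arr < 0):
            raise ValueError("times must be non-negative")
        self._ensure_grid(float(arr.max(initial=0.0)))
        out = np.exp(-np.interp(arr, self._grid, self._cumhaz))
        return float(out[0]) if scalar else out


def apply_background_mortality(
    os_curve: ParametricCurve, life_table: LifeTable, start_age_years: float = 50.0
) -> BlendedSurvival:
    return BlendedSurvival(os_curve, life_table, start_age_years)


@dataclass(frozen=True)
class Trace:
    """Per-cycle state memberships of the cohort (fractions of 1).

    Arrays are indexed by cycle k = 1..n; ``t_days`` holds the evaluation
    times.  ``on_treatment`` is the drug-bearing share of the PFS state
    (initially equal to it; see :func:`on_treatment_occupancy`).
    """

    t_days: np.ndarray
    pfs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    new_deaths: np.ndarray
    on_treatment: np.ndarray

    def __post_init__(self) -> None:
        for name in ("t_days", "pfs", "pd", "dead", "new_deaths", "on_treatment"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t_days)
        for name in ("pfs", "pd", "dead", "new_deaths", "on_treatment"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"trace column {name} has wrong length")
        total = self.pfs + self.pd + self.dead
        if np.any(np.abs(total - 1.0) > 1e-9):
            raise ValueError("state memberships must sum to 1 every cycle")
        if np.any(np.diff(self.dead) < -1e-12):
            raise ValueError("dead membership must be non-decreasing")
        if np.any(self.new_deaths < -1e-12):
            raise ValueError("new_deaths must be non-negative")
        if np.any(self.on_treatment > self.pfs + 1e-12):
            raise ValueError("on-treatment occupancy cannot exceed PFS membership")

    @property
    def n_cycles(self) -> int:
        return len(self.t_days)

    @property
    def alive(self) -> np.ndarray:
        return self.pfs + self.pd

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(1, self.n_cycles + 1),
                "t_days": self.t_days,
                "pfs": self.pfs,
                "pd": self.pd,
                "dead": self.dead,
                "new_deaths": self.new_deaths,
                "on_treatment": self.on_treatment,
            }
        )


def partition_memberships(os_surv, pfs_surv, plan: CyclePlan) -> Trace:
    """Read state occupancy off the two survival curves at each cycle.

    ``os_surv`` and ``pfs_surv`` are callables (or curves) returning S(t)
    for t in days.  PFS membership is clamped at OS survival; if the PFS
    curve exceeds OS anywhere on the grid a warning reports the range.
    """
    t = plan.eval_times_days
    s_os = np.clip(np.asarray(os_surv(t), dtype=float), 0.0, 1.0)
    s_pfs = np.clip(np.asarray(pfs_surv(t), dtype=float), 0.0, 1.0)
    crossed = s_pfs > s_os + 1e-12
    if np.any(crossed):
        lo, hi = t[crossed].min(), t[crossed].max()
        warnings.warn(
            f"PFS curve exceeds OS on [{lo:.1f}, {hi:.1f}] days; clamping PFS to OS",
            stacklevel=2,
        )
    pfs = np.minimum(s_pfs, s_os)
    dead = 1.0 - s_os
    pd_ = 1.0 - pfs - dead
    new_deaths = np.diff(dead, prepend=0.0)
    new_deaths = np.maximum(new_deaths, 0.0)
    return Trace(
        t_days=t,
        pfs=pfs,
        pd=pd_,
        dead=dead,
        new_deaths=new_deaths,
        on_treatment=pfs.copy(),
    )


def on_treatment_occupancy(trace: Trace, cap_cycles: int | None) -> Trace:
    """Limit drug-bearing occupancy to the first ``cap_cycles`` cycles."""
    if cap_cycles is None:
        on = trace.pfs.copy()
    else:
        if cap_cycles < 0:
            raise ValueError("treatment cap cannot be negative")
        on = trace.pfs.copy()
        on[int(cap_cycles):] = 0.0
    return replace(trace, on_treatment=on)


def export_trace(trace: Trace, plan: CyclePlan, path) -> None:
    df = trace.to_frame()
    df["discount_factor"] = plan.discount_factors()
    df.to_csv(path, index=False)
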