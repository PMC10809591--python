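"""Discounted cost and effect accrual over a cohort trace, and ICERs.

Costs are accrued per cycle against the state occupancy of a
:class:`~psmcea.psm_engine.Trace`: drug acquisition against on-treatment
occupancy, scheduled laboratory/imaging monitoring against the alive
share, a one-time adverse-event lump sum (incidence times unit cost,
charged in cycle 1 on the assumption that serious events cluster at
treatment start), and a terminal-care cost attached to each cycle's new
deaths.  Life-years and QALYs integrate the alive occupancy (utility
weighted for QALYs) over the cycle grid.  Everything is discounted at the
cycle's evaluation time with the standard annual compound factor
1/(1+r)^(t/365.25).

All monetary amounts are USD (the source prices were converted at a fixed
6.73 RMB/USD).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .curves import DAYS_PER_YEAR
from .psm_engine import CyclePlan, Trace

__all__ = [
    "discount_factor",
    "AEEvent",
    "StrategyInputs",
    "mixed_drug_cost",
    "UtilityInputs",
    "CostBreakdown",
    "EffectTotals",
    "StrategyTotals",
    "CEResult",
    "accrue_costs",
    "accrue_effects",
    "evaluate_strategy",
    "compute_icer",
    "net_monetary_benefit",
]


def discount_factor(t_days, annual_rate: float):
    """Discount factor 1/(1 + r)^(t/365.25) at time t (days)."""
    if annual_rate <= -1.0:
        raise ValueError("annual discount rate must exceed -1")
    t = np.asarray(t_days, dtype=float)
    if np.any(t < 0):
        raise ValueError("discount times must be non-negative")
    out = (1.0 + annual_rate) ** (-t / DAYS_PER_YEAR)
    return float(out) if np.ndim(t_days) == 0 else out


@dataclass(frozen=True)
class AEEvent:
    """A grade >=3 adverse event: incidence and one-off management cost."""

    name: str
    probability: float
    unit_cost: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"AE probability must be in [0,1], got {self.probability}")
        if self.unit_cost < 0:
            raise ValueError("AE unit cost cannot be negative")


@dataclass(frozen=True)
class StrategyInputs:
    """Per-strategy cost inputs on the 21-day cycle grid (USD)."""

    name: str
    drug_cost_per_cycle: float
    ae_events: tuple[AEEvent, ...] = ()
    imaging_cost: float = 207.25
    lab_cost: float = 11.89
    imaging_interval: int = 3
    lab_interval: int = 1
    terminal_care_cost: float = 1460.30
    treatment_cap: int | None = None

    def __post_init__(self) -> None:
        for fld in ("drug_cost_per_cycle", "imaging_cost", "lab_cost", "terminal_care_cost"):
            if getattr(self, fld) < 0:
                raise ValueError(f"{fld} cannot be negative")
        for fld in ("imaging_interval", "lab_interval"):
            if getattr(self, fld) < 1:
                raise ValueError(f"{fld} must be a positive number of cycles")
        if self.treatment_cap is not None and self.treatment_cap < 0:
            raise ValueError("treatment cap cannot be negative")
        object.__setattr__(self, "ae_events", tuple(self.ae_events))

    def with_drug_cost(self, cost: float) -> "StrategyInputs":
        return replace(self, drug_cost_per_cycle=cost)


def mixed_drug_cost(costs: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted per-cycle cost of a multi-regimen comparator arm."""
    c = np.asarray(costs, dtype=float)
    w = np.asarray(weights, dtype=float)
    if c.shape != w.shape:
        raise ValueError("costs and weights must have equal length")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("mix weights must be non-negative and sum to 1")
    if np.any(c < 0):
        raise ValueError("drug costs cannot be negative")
    return float(c @ w)


@dataclass(frozen=True)
class UtilityInputs:
    u_pfs: float = 0.76
    u_pd: float = 0.35
    u_dead: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.u_dead <= self.u_pd <= self.u_pfs <= 1.0:
            raise ValueError(
                "utilities must satisfy 0 <= u_dead <= u_pd <= u_pfs <= 1, got "
                f"({self.u_pfs}, {self.u_pd}, {self.u_dead})"
            )


@dataclass(frozen=True)
class CostBreakdown:
    drug: float
    adverse_events: float
    imaging: float
    laboratory: float
    terminal_care: float

    @property
    def total(self) -> float:
        return (
            self.drug
            + self.adverse_events
            + self.imaging
            + self.laboratory
            + self.terminal_care
        )


class EffectTotals(NamedTuple):
    ly: float
    qaly: float


@dataclass(frozen=True)
class StrategyTotals:
    name: str
    cost: float
    ly: float
    qaly: float
    breakdown: CostBreakdown | None = None


def _check_lengths(trace: Trace, plan: CyclePlan) -> None:
    if trace.n_cycles != plan.n_cycles:
        raise ValueError(
            f"trace has {trace.n_cycles} cycles but plan expects {plan.n_cycles}"
        )


def accrue_costs(
    trace: Trace,
    inputs: StrategyInputs,
    plan: CyclePlan,
    drug_cycle_mask: np.ndarray | None = None,
) -> CostBreakdown:
    """Discounted total cost with a per-component breakdown.

    ``drug_cycle_mask`` (booleans per cycle) restricts which cycles incur
    drug acquisition cost; it exists for donation-style payment schedules
    and defaults to all cycles.
    """
    _check_lengths(trace, plan)
    d = plan.discount_factors()
    cycles = np.arange(1, plan.n_cycles + 1)

    on_drug = trace.on_treatment
    if drug_cycle_mask is not None:
        mask = np.asarray(drug_cycle_mask, dtype=bool)
        if len(mask) != plan.n_cycles:
            raise ValueError("drug_cycle_mask length must match the cycle plan")
        on_drug = on_drug * mask
    drug = float(inputs.drug_cost_per_cycle * np.sum(on_drug * d))

    ae_lump = sum(ev.probability * ev.unit_cost for ev in inputs.ae_events)
    ae = float(ae_lump * d[0])

    imaging_due = (cycles % inputs.imaging_interval) == 0
    lab_due = (cycles % inputs.lab_interval) == 0
    imaging = float(inputs.imaging_cost * np.sum(trace.alive * imaging_due * d))
    laboratory = float(inputs.lab_cost * np.sum(trace.alive * lab_due * d))

    terminal = float(inputs.terminal_care_cost * np.sum(trace.new_deaths * d))

    return CostBreakdown(drug, ae, imaging, laboratory, terminal)


def accrue_effects(
    trace: Trace, utilities: UtilityInputs, plan: CyclePlan
) -> EffectTotals:
    """Discounted life-years and QALYs over the trace."""
    _check_lengths(trace, plan)
    d = plan.discount_factors()
    dt = plan.cycle_years
    ly = float(np.sum(trace.alive * dt * d))
    qaly = float(
        np.sum((utilities.u_pfs * trace.pfs + utilities.u_pd * trace.pd) * dt * d)
    )
    return EffectTotals(ly=ly, qaly=qaly)


def evaluate_strategy(
    trace: Trace,
    inputs: StrategyInputs,
    utilities: UtilityInputs,
    plan: CyclePlan,
    drug_cycle_mask: np.ndarray | None = None,
) -> StrategyTotals:
    costs = accrue_costs(trace, inputs, plan, drug_cycle_mask)
    eff = accrue_effects(trace, utilities, plan)
    return StrategyTotals(inputs.name, costs.total, eff.ly, eff.qaly, costs)


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of a reference strategy against a comparator."""

    reference: StrategyTotals
    comparator: StrategyTotals
    incr_cost: float
    incr_ly: float
    incr_qaly: float
    icer_per_ly: float
    icer_per_qaly: float
    dominance: str
    cost_effective: bool
    wtp: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in (self.comparator, self.reference):
            rows.append(
                {"strategy": s.name, "cost": s.cost, "ly": s.ly, "qaly": s.qaly}
            )
        df = pd.DataFrame(rows)
        for col, val in (
            ("incr_cost", self.incr_cost),
            ("incr_ly", self.incr_ly),
            ("incr_qaly", self.incr_qaly),
            ("icer_per_ly", self.icer_per_ly),
            ("icer_per_qaly", self.icer_per_qaly),
        ):
            df[col] = [np.nan, val]
        df["dominance"] = ["", self.dominance]
        return df


_EFFECT_TOL = 1e-12


def compute_icer(
    reference: StrategyTotals, comparator: StrategyTotals, wtp: float
) -> CEResult:
    """Incremental cost, effects, ICERs and dominance classification.

    The ICER is undefined (NaN) when the effect difference is zero; a
    strategy that is cheaper with equal effects still dominates on cost.
    Dominance uses QALYs as the effect measure.
    """
    d_cost = reference.cost - comparator.cost
    d_ly = reference.ly - comparator.ly
    d_qaly = reference.qaly - comparator.qaly

    icer_ly = d_cost / d_ly if abs(d_ly) > _EFFECT_TOL else float("nan")
    icer_qaly = d_cost / d_qaly if abs(d_qaly) > _EFFECT_TOL else float("nan")

    if abs(d_qaly) <= _EFFECT_TOL and abs(d_cost) <= _EFFECT_TOL:
        dominance = "none"
    elif d_cost <= _EFFECT_TOL and d_qaly >= -_EFFECT_TOL:
        dominance = "dominant"
    elif d_cost >= -_EFFECT_TOL and d_qaly <= _EFFECT_TOL:
        dominance = "dominated"
    else:
        dominance = "none"

    cost_effective = dominance == "dominant" or (
        d_qaly > _EFFECT_TOL and icer_qaly <= wtp
    )
    return CEResult(
        reference=reference,
        comparator=comparator,
        incr_cost=d_cost,
        incr_ly=d_ly,
        incr_qaly=d_qaly,
        icer_per_ly=icer_ly,
        icer_per_qaly=icer_qaly,
        dominance=dominance,
        cost_effective=cost_effective,
        wtp=wtp,
    )


def net_monetary_benefit(totals: StrategyTotals, wtp: float) -> float:
    """NMB = WTP * QALY - cost; positive incremental NMB means cost-effective."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * totals.qaly - totals.cost
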