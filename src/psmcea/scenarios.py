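"""Scenario analyses: donation payment schedule, price cuts, discount rates.

Three policy scenarios are evaluated against the base case:

1. A philanthropic donation program for the reference drug: the patient
   pays for cycles 1-2, receives cycles 3-4 free, pays for cycles 5-6, and
   all further cycles up to the 35-cycle cap are donated.  Only paid
   cycles accrue drug cost; everything else in the model is unchanged.
2. A uniform drug-price reduction (default 60%), reflecting the price
   cuts typically negotiated for oncology drugs entering a national
   reimbursement list.
3. Alternative annual discount rates (3% and 8%) applied to both costs
   and effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import CEResult, StrategyInputs
from .model import PSModel
from .psm_engine import CyclePlan, Trace

__all__ = [
    "DonationSchedule",
    "default_donation_schedule",
    "donation_drug_cost",
    "apply_price_reduction",
    "default_scenarios",
    "run_scenarios",
]


@dataclass(frozen=True)
class DonationSchedule:
    """Which cycles the patient pays for under a drug-donation program."""

    paid_cycles: frozenset[int] = frozenset({1, 2, 5, 6})
    donated_cycles: frozenset[int] = field(
        default_factory=lambda: frozenset({3, 4} | set(range(7, 36)))
    )
    cap_cycles: int = 35

    def __post_init__(self) -> None:
        object.__setattr__(self, "paid_cycles", frozenset(self.paid_cycles))
        object.__setattr__(self, "donated_cycles", frozenset(self.donated_cycles))
        if self.paid_cycles & self.donated_cycles:
            raise ValueError("paid and donated cycle sets must be disjoint")
        covered = self.paid_cycles | self.donated_cycles
        if covered and (min(covered) < 1 or max(covered) > self.cap_cycles):
            raise ValueError(f"cycle indices must lie in 1..{self.cap_cycles}")

    def paid_mask(self, n_cycles: int) -> np.ndarray:
        """Boolean mask (cycle 1..n) of cycles that incur drug cost."""
        cycles = np.arange(1, n_cycles + 1)
        return np.isin(cycles, sorted(self.paid_cycles))


def default_donation_schedule() -> DonationSchedule:
    return DonationSchedule()


def donation_drug_cost(
    trace: Trace, price_per_cycle: float, schedule: DonationSchedule, plan: CyclePlan
) -> float:
    """Discounted drug cost when only the paid cycles are charged."""
    if price_per_cycle < 0:
        raise ValueError("price cannot be negative")
    mask = schedule.paid_mask(plan.n_cycles)
    d = plan.discount_factors()
    return float(price_per_cycle * np.sum(trace.on_treatment * mask * d))


def apply_price_reduction(inputs: StrategyInputs, fraction: float) -> StrategyInputs:
    """Scale the per-cycle drug cost by (1 - fraction); all else unchanged."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"price-reduction fraction must be in [0,1], got {fraction}")
    return inputs.with_drug_cost(inputs.drug_cost_per_cycle * (1.0 - fraction))


def default_scenarios() -> list[dict]:
    return [
        {"name": "philanthropic drug donation program", "kind": "donation"},
        {"name": "price dropped by 60%", "kind": "price_reduction", "fraction": 0.6},
        {"name": "3% discount", "kind": "discount", "rate": 0.03},
        {"name": "8% discount", "kind": "discount", "rate": 0.08},
    ]


def _evaluate_scenario(model: PSModel, scenario: dict) -> CEResult:
    kind = scenario.get("kind")
    if kind == "donation":
        schedule = scenario.get("schedule", default_donation_schedule())
        mask = schedule.paid_mask(model.config.plan.n_cycles)
        return model.evaluate(reference_drug_mask=mask)
    if kind == "price_reduction":
        fraction = float(scenario["fraction"])
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"price-reduction fraction must be in [0,1], got {fraction}")
        base_price = model.base_params()["pembrolizumab_cost_per_cycle"]
        return model.evaluate(
            {"pembrolizumab_cost_per_cycle": base_price * (1.0 - fraction)}
        )
    if kind == "discount":
        return model.evaluate({"discount_rate": float(scenario["rate"])})
    raise ValueError(f"unknown scenario kind {kind!r} in {scenario.get('name')!r}")


def run_scenarios(model: PSModel, scenario_list: list[dict] | None = None) -> pd.DataFrame:
    """Base case plus one row pair per scenario, in results-table layout.

    Each scenario contributes a comparator row and a reference row with the
    incremental cost/effect and ICER (per QALY) on the reference row.
    """
    if scenario_list is None:
        scenario_list = default_scenarios()
    entries = [("base case", model.evaluate())]
    entries += [(sc["name"], _evaluate_scenario(model, sc)) for sc in scenario_list]
    rows = []
    for name, res in entries:
        rows.append(
            {
                "scenario": name,
                "strategy": res.comparator.name,
                "cost": res.comparator.cost,
                "incr_cost": np.nan,
                "qaly": res.comparator.qaly,
                "incr_qaly": np.nan,
                "icer_per_qaly": np.nan,
                "remarks": "",
            }
        )
        rows.append(
            {
                "scenario": name,
                "strategy": res.reference.name,
                "cost": res.reference.cost,
                "incr_cost": res.incr_cost,
                "qaly": res.reference.qaly,
                "incr_qaly": res.incr_qaly,
                "icer_per_qaly": res.icer_per_qaly,
                "remarks": res.dominance if res.dominance != "none" else "",
            }
        )
    return pd.DataFrame(rows)
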