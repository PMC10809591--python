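"""The configured two-strategy model: traces precomputed, economics on top.

`PSModel` wires the pieces together for sensitivity analysis: survival
curves (hence state-occupancy traces) are structural and computed once,
while cost and utility parameters can be overridden per evaluation.  An
evaluation therefore costs a handful of vector operations over the 87-cycle
grid, which keeps a 1000-iteration probabilistic sensitivity analysis
essentially instantaneous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import defaults as d
from .curves import ParametricCurve, curve_from_median
from .economics import (
    AEEvent,
    CEResult,
    StrategyInputs,
    UtilityInputs,
    compute_icer,
    evaluate_strategy,
    mixed_drug_cost,
)
from .psm_engine import (
    CyclePlan,
    LifeTable,
    Trace,
    apply_background_mortality,
    build_cycle_plan,
    on_treatment_occupancy,
    partition_memberships,
    synthetic_life_table,
)

__all__ = ["ArmCurves", "ModelConfig", "default_model_config", "PSModel"]

REFERENCE = "pembrolizumab"
COMPARATOR = "chemotherapy"


@dataclass(frozen=True)
class ArmCurves:
    """OS and PFS survival inputs for one strategy (day-based callables)."""

    os_curve: ParametricCurve
    pfs_curve: ParametricCurve


@dataclass(frozen=True)
class ModelConfig:
    curves: dict[str, ArmCurves]
    plan: CyclePlan = field(default_factory=build_cycle_plan)
    wtp: float = d.WTP_PER_QALY
    reference: str = REFERENCE
    comparator: str = COMPARATOR
    use_background_mortality: bool = True
    life_table: LifeTable | None = None
    start_age_years: float = d.START_AGE_YEARS
    treatment_caps: dict[str, int | None] = field(
        default_factory=lambda: {
            REFERENCE: d.PEMBROLIZUMAB_CAP_CYCLES,
            COMPARATOR: None,
        }
    )

    def __post_init__(self) -> None:
        for arm in (self.reference, self.comparator):
            if arm not in self.curves:
                raise ValueError(f"no survival curves configured for arm {arm!r}")
        if self.wtp <= 0:
            raise ValueError("willingness-to-pay threshold must be positive")


def default_model_config(**overrides) -> ModelConfig:
    """Base-case model: curves calibrated from the published medians."""
    curves = {
        arm: ArmCurves(
            os_curve=curve_from_median(
                "exponential", d.OS_MEDIANS_MONTHS[arm]
            ).to_unit("days"),
            pfs_curve=curve_from_median(
                "lognormal", d.PFS_MEDIANS_MONTHS[arm], d.PFS_LOGNORMAL_SIGMA
            ).to_unit("days"),
        )
        for arm in (REFERENCE, COMPARATOR)
    }
    return ModelConfig(curves=curves, **overrides)


#: every overridable parameter name with its base value resolver
def _base_params() -> dict[str, float]:
    params = {
        "pembrolizumab_cost_per_cycle": d.DRUG_COSTS["pembrolizumab"],
        "anemia_cost": d.AE_COSTS["anemia"],
        "neutrocytopenia_cost": d.AE_COSTS["neutrocytopenia"],
        "imaging_cost": d.IMAGING_COST,
        "lab_cost": d.LAB_COST,
        "terminal_care_cost": d.TERMINAL_CARE_COST,
        "utility_pfs": d.UTILITY_PFS,
        "utility_pd": d.UTILITY_PD,
        "discount_rate": d.DISCOUNT_RATE,
    }
    for drug in d.CHEMO_DRUGS:
        params[f"{drug}_cost_per_cycle"] = d.DRUG_COSTS[drug]
    for arm in (REFERENCE, COMPARATOR):
        for ae in ("anemia", "neutrocytopenia"):
            params[f"p_{ae}_{arm}"] = d.AE_PROBS[arm][ae]
    return params


class PSModel:
    """Two-strategy partitioned-survival cost-effectiveness model."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.traces: dict[str, Trace] = {}
        life_table = config.life_table
        if config.use_background_mortality and life_table is None:
            life_table = synthetic_life_table()
        for arm in (config.reference, config.comparator):
            arm_curves = config.curves[arm]
            os_fn = arm_curves.os_curve.to_unit("days")
            if config.use_background_mortality:
                os_fn = apply_background_mortality(
                    os_fn, life_table, config.start_age_years
                )
            trace = partition_memberships(
                os_fn, arm_curves.pfs_curve.to_unit("days"), config.plan
            )
            self.traces[arm] = on_treatment_occupancy(
                trace, config.treatment_caps.get(arm)
            )

    # -- parameter surface --------------------------------------------------

    def base_params(self) -> dict[str, float]:
        return dict(_base_params())

    def _resolve(self, overrides: dict[str, float] | None) -> dict[str, float]:
        params = self.base_params()
        if overrides:
            unknown = set(overrides) - set(params)
            if unknown:
                raise KeyError(
                    f"unknown model parameter(s) {sorted(unknown)}; "
                    f"known: {sorted(params)}"
                )
            params.update(overrides)
        return params

    def strategy_inputs(self, params: dict[str, float]) -> dict[str, StrategyInputs]:
        chemo_cost = mixed_drug_cost(
            [params[f"{drug}_cost_per_cycle"] for drug in d.CHEMO_DRUGS],
            d.CHEMO_MIX_WEIGHTS,
        )
        common = dict(
            imaging_cost=params["imaging_cost"],
            lab_cost=params["lab_cost"],
            imaging_interval=d.IMAGING_INTERVAL_CYCLES,
            lab_interval=d.LAB_INTERVAL_CYCLES,
            terminal_care_cost=params["terminal_care_cost"],
        )

        def _aes(arm: str) -> tuple[AEEvent, ...]:
            return tuple(
                AEEvent(ae, params[f"p_{ae}_{arm}"], params[f"{ae}_cost"])
                for ae in ("anemia", "neutrocytopenia")
            )

        cfg = self.config
        return {
            cfg.reference: StrategyInputs(
                name=cfg.reference,
                drug_cost_per_cycle=params["pembrolizumab_cost_per_cycle"],
                ae_events=_aes(cfg.reference),
                treatment_cap=cfg.treatment_caps.get(cfg.reference),
                **common,
            ),
            cfg.comparator: StrategyInputs(
                name=cfg.comparator,
                drug_cost_per_cycle=chemo_cost,
                ae_events=_aes(cfg.comparator),
                treatment_cap=cfg.treatment_caps.get(cfg.comparator),
                **common,
            ),
        }

    # -- evaluation ----------------------------------------------------------

    def evaluate(
        self,
        overrides: dict[str, float] | None = None,
        *,
        reference_drug_mask: np.ndarray | None = None,
    ) -> CEResult:
        """Full model evaluation at a parameter point.

        ``reference_drug_mask`` optionally restricts which cycles incur
        drug cost for the reference strategy (donation-style payment
        schedules).
        """
        params = self._resolve(overrides)
        plan = self.config.plan.with_discount(params["discount_rate"])
        utilities = UtilityInputs(u_pfs=params["utility_pfs"], u_pd=params["utility_pd"])
        inputs = self.strategy_inputs(params)
        cfg = self.config
        ref = evaluate_strategy(
            self.traces[cfg.reference],
            inputs[cfg.reference],
            utilities,
            plan,
            drug_cycle_mask=reference_drug_mask,
        )
        comp = evaluate_strategy(
            self.traces[cfg.comparator], inputs[cfg.comparator], utilities, plan
        )
        return compute_icer(ref, comp, cfg.wtp)
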