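"""Deterministic and probabilistic sensitivity analysis.

One-way analysis re-evaluates the full model at each parameter's lower and
upper bound with everything else held at base, producing a tornado table
ordered by ICER span.  Probabilistic analysis draws all parameters jointly
and independently -- gamma distributions for costs, beta for utilities and
incidences, moment-matched so that the distribution mean equals the base
value and the SD equals (high - low)/3.92 (the printed interval read as a
95% range) -- and summarises the draws as a cost-effectiveness plane and a
cost-effectiveness acceptability curve (CEAC: the fraction of iterations
with positive incremental net monetary benefit at each willingness-to-pay).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import defaults as d
from .model import COMPARATOR, REFERENCE, PSModel

__all__ = [
    "ParamSpec",
    "default_param_specs",
    "moment_matched_distribution",
    "one_way_dsa",
    "PSAResults",
    "run_psa",
    "ceac",
    "ce_plane",
]


@dataclass(frozen=True)
class ParamSpec:
    """One model parameter with its base value, range and PSA distribution."""

    name: str
    base: float
    low: float
    high: float
    distribution: str = "gamma"  # gamma | beta | fixed
    range_source: str = "interval"  # interval | pm20

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"{self.name}: need low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )
        if self.distribution not in ("gamma", "beta", "fixed"):
            raise ValueError(f"{self.name}: unknown distribution {self.distribution!r}")
        if self.distribution == "beta" and not (0.0 <= self.base <= 1.0):
            raise ValueError(
                f"{self.name}: beta distribution requires a base in [0,1], "
                f"got {self.base}"
            )

    @property
    def sd(self) -> float:
        return (self.high - self.low) / 3.92

    @classmethod
    def pm20(cls, name: str, base: float, distribution: str) -> "ParamSpec":
        """Range as +/-20% of base (used when no interval is published)."""
        lo, hi = 0.8 * base, 1.2 * base
        if distribution == "beta":
            hi = min(hi, 1.0)
        return cls(name, base, lo, hi, distribution, range_source="pm20")


def default_param_specs(include_discount: bool = False) -> list[ParamSpec]:
    """The packaged sensitivity-analysis parameter table.

    Costs are gamma-distributed, utilities and incidences beta; adverse
    -event incidences have no published interval and use +/-20% of base.
    The discount rate is treated as structural and excluded from PSA
    unless ``include_discount``; in one-way analysis it spans 0-8%.
    """
    specs = [
        ParamSpec(
            "pembrolizumab_cost_per_cycle",
            d.DRUG_COSTS["pembrolizumab"],
            *d.DRUG_COST_RANGES["pembrolizumab"],
            "gamma",
        ),
    ]
    for drug in d.CHEMO_DRUGS:
        specs.append(
            ParamSpec(
                f"{drug}_cost_per_cycle", d.DRUG_COSTS[drug], *d.DRUG_COST_RANGES[drug], "gamma"
            )
        )
    for ae in ("anemia", "neutrocytopenia"):
        specs.append(ParamSpec(f"{ae}_cost", d.AE_COSTS[ae], *d.AE_COST_RANGES[ae], "gamma"))
    specs += [
        ParamSpec("imaging_cost", d.IMAGING_COST, *d.IMAGING_COST_RANGE, "gamma"),
        ParamSpec("lab_cost", d.LAB_COST, *d.LAB_COST_RANGE, "gamma"),
        ParamSpec(
            "terminal_care_cost", d.TERMINAL_CARE_COST, *d.TERMINAL_CARE_COST_RANGE, "gamma"
        ),
        ParamSpec("utility_pfs", d.UTILITY_PFS, *d.UTILITY_PFS_RANGE, "beta"),
        ParamSpec("utility_pd", d.UTILITY_PD, *d.UTILITY_PD_RANGE, "beta"),
    ]
    for arm in (REFERENCE, COMPARATOR):
        for ae in ("anemia", "neutrocytopenia"):
            specs.append(ParamSpec.pm20(f"p_{ae}_{arm}", d.AE_PROBS[arm][ae], "beta"))
    if include_discount:
        specs.append(
            ParamSpec("discount_rate", d.DISCOUNT_RATE, *d.DISCOUNT_RANGE, "beta")
        )
    return specs


class _Sampler:
    """Moment-matched sampler for one parameter."""

    def __init__(self, spec: ParamSpec):
        self.spec = spec
        self.mean = spec.base
        self.sd = 0.0 if spec.distribution == "fixed" else spec.sd
        if self.sd == 0.0:
            self.kind = "point"
        elif spec.distribution == "gamma":
            self.kind = "gamma"
            if self.mean <= 0:
                raise ValueError(f"{spec.name}: gamma needs a positive base value")
            self.shape = self.mean**2 / self.sd**2
            self.scale = self.sd**2 / self.mean
        else:  # beta
            if not 0.0 < self.mean < 1.0:
                raise ValueError(
                    f"{spec.name}: beta with spread needs base in (0,1), got {self.mean}"
                )
            common = self.mean * (1 - self.mean) / self.sd**2 - 1.0
            if common <= 0:
                raise ValueError(
                    f"{spec.name}: infeasible beta moments (mean {self.mean}, "
                    f"sd {self.sd}): variance exceeds mean(1-mean)"
                )
            self.kind = "beta"
            self.alpha = self.mean * common
            self.beta = self.alpha * (1 - self.mean) / self.mean

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "point":
            return np.full(n, self.mean)
        if self.kind == "gamma":
            return rng.gamma(self.shape, self.scale, size=n)
        return rng.beta(self.alpha, self.beta, size=n)


def moment_matched_distribution(spec: ParamSpec) -> _Sampler:
    """Sampler whose mean is the base value and SD is (high - low)/3.92."""
    return _Sampler(spec)


def one_way_dsa(model: PSModel, specs: list[ParamSpec], wtp: float) -> pd.DataFrame:
    """Tornado table: ICER (per QALY) at each parameter's bounds.

    Rows are sorted by descending ICER span; ``crosses_wtp`` flags
    parameters whose bounds disagree on cost-effectiveness at ``wtp``.
    """
    known = model.base_params()
    rows = []
    for spec in specs:
        if spec.name not in known:
            raise KeyError(f"parameter {spec.name!r} unknown to the model")
        res_lo = model.evaluate({spec.name: spec.low})
        res_hi = model.evaluate({spec.name: spec.high})
        icer_lo, icer_hi = res_lo.icer_per_qaly, res_hi.icer_per_qaly
        span = abs(icer_hi - icer_lo)
        rows.append(
            {
                "parameter": spec.name,
                "base": spec.base,
                "low": spec.low,
                "high": spec.high,
                "icer_low": icer_lo,
                "icer_high": icer_hi,
                "span": span,
                "crosses_wtp": res_lo.cost_effective != res_hi.cost_effective,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("span", ascending=False, na_position="last").reset_index(
        drop=True
    )


@dataclass(frozen=True)
class PSAResults:
    """Joint parameter draws and the model outcome of every iteration."""

    draws: pd.DataFrame
    outcomes: pd.DataFrame  # cost/qaly per strategy + incrementals per iteration
    n_iterations: int
    seed: int

    def __post_init__(self) -> None:
        for df in (self.draws, self.outcomes):
            if len(df) != self.n_iterations:
                raise ValueError("PSA tables must have one row per iteration")
            if df.isna().any().any():
                raise ValueError("PSA tables must not contain missing values")


def run_psa(
    model: PSModel, specs: list[ParamSpec], n_iter: int = 1000, seed: int = 0
) -> PSAResults:
    """Monte-Carlo parameter sampling with full model evaluation per draw.

    Parameters are drawn independently, in the order of ``specs``, from a
    single seeded generator, so results are reproducible bit-for-bit.
    Survival curves are structural and held fixed.
    """
    if n_iter < 1:
        raise ValueError("need at least one PSA iteration")
    rng = np.random.default_rng(seed)
    samplers = [moment_matched_distribution(s) for s in specs]
    draws = pd.DataFrame(
        {s.spec.name: s.rvs(n_iter, rng) for s in samplers}
    )
    records = []
    for i in range(n_iter):
        overrides = {name: float(draws[name].iloc[i]) for name in draws.columns}
        try:
            res = model.evaluate(overrides)
        except Exception as exc:  # noqa: BLE001 - re-raise with context per contract
            raise RuntimeError(
                f"PSA iteration {i} failed at draw {overrides}: {exc}"
            ) from exc
        records.append(
            {
                "cost_reference": res.reference.cost,
                "qaly_reference": res.reference.qaly,
                "cost_comparator": res.comparator.cost,
                "qaly_comparator": res.comparator.qaly,
                "incr_cost": res.incr_cost,
                "incr_qaly": res.incr_qaly,
            }
        )
    return PSAResults(draws, pd.DataFrame(records), n_iter, seed)


def ceac(results: PSAResults, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve for the reference strategy.

    For each willingness-to-pay, the probability is the fraction of
    iterations with positive incremental net monetary benefit
    (wtp * incremental QALY - incremental cost > 0).
    """
    grid = np.atleast_1d(np.asarray(wtp_grid, dtype=float))
    if len(grid) == 0:
        raise ValueError("CEAC needs a non-empty willingness-to-pay grid")
    dq = results.outcomes["incr_qaly"].to_numpy()
    dc = results.outcomes["incr_cost"].to_numpy()
    prob = [(w * dq - dc > 0).mean() for w in grid]
    return pd.DataFrame({"wtp": grid, "probability": prob})


def ce_plane(results: PSAResults) -> pd.DataFrame:
    """Cost-effectiveness plane: one (incremental QALY, incremental cost) per draw."""
    return results.outcomes[["incr_qaly", "incr_cost"]].copy()
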