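"""Run configuration: a single YAML file resolving every model input.

Each survival endpoint accepts one input mode:

- ``median``: calibrate a curve from a published median (exponential or
  lognormal),
- ``ipd``: fit all six parametric families to an individual-patient-data
  CSV (columns time_days, event, arm) and select by AIC/BIC,
- ``km``: reconstruct pseudo-IPD from a digitized Kaplan-Meier CSV
  (columns time_days, survival), then fit and select as above.

Invalid fields are reported with their dotted path and a reason.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .curves import ParametricCurve, curve_from_median
from .model import ArmCurves, ModelConfig, PSModel
from .psm_engine import LifeTable, build_cycle_plan
from .survival_fitting import (
    fit_all_families,
    reconstruct_ipd_from_km,
    select_model,
)
from .synthetic_ipd import IPDataset, KMDigitized

__all__ = ["RunConfig", "load_config", "default_config_path", "build_model"]


class ConfigError(ValueError):
    def __init__(self, path: str, reason: str):
        super().__init__(f"config field {path!r}: {reason}")


def default_config_path() -> Path:
    return Path(importlib.resources.files("psmcea") / "data" / "default_config.yaml")


@dataclass(frozen=True)
class RunConfig:
    raw: dict
    base_dir: Path = field(default_factory=Path.cwd)

    def __post_init__(self) -> None:
        _validate_raw(self.raw)

    # typed accessors -------------------------------------------------------

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def wtp(self) -> float:
        return float(self.raw["wtp_per_qaly"])

    @property
    def reference(self) -> str:
        return self.raw.get("reference", "pembrolizumab")

    @property
    def comparator(self) -> str:
        return self.raw.get("comparator", "chemotherapy")

    @property
    def psa_settings(self) -> dict:
        return self.raw.get("psa", {"enabled": True, "n_iterations": 1000})

    @property
    def dsa_enabled(self) -> bool:
        return bool(self.raw.get("dsa", {}).get("enabled", True))

    @property
    def scenario_list(self) -> list[dict]:
        return list(self.raw.get("scenarios", []))

    def resolve_path(self, p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else self.base_dir / path


def _validate_raw(raw: dict) -> None:
    if not isinstance(raw, dict):
        raise ConfigError("<root>", "configuration must be a mapping")
    if "wtp_per_qaly" not in raw:
        raise ConfigError("wtp_per_qaly", "missing")
    if float(raw["wtp_per_qaly"]) <= 0:
        raise ConfigError("wtp_per_qaly", "must be positive")
    surv = raw.get("survival")
    if not isinstance(surv, dict) or not surv:
        raise ConfigError("survival", "must map arm names to endpoint inputs")
    for arm, endpoints in surv.items():
        for ep in ("os", "pfs"):
            if ep not in endpoints:
                raise ConfigError(f"survival.{arm}.{ep}", "missing endpoint input")
            mode = endpoints[ep].get("mode")
            if mode not in ("median", "ipd", "km"):
                raise ConfigError(
                    f"survival.{arm}.{ep}.mode",
                    f"must be one of median/ipd/km, got {mode!r}",
                )
    ref = raw.get("reference", "pembrolizumab")
    comp = raw.get("comparator", "chemotherapy")
    for role, arm in (("reference", ref), ("comparator", comp)):
        if arm not in surv:
            raise ConfigError(role, f"arm {arm!r} has no survival inputs")


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration (the packaged default if no path)."""
    p = Path(path) if path is not None else default_config_path()
    with open(p) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(raw=raw, base_dir=p.parent.resolve())


def _curve_from_block(cfg: RunConfig, arm: str, endpoint: str) -> ParametricCurve:
    block = cfg.raw["survival"][arm][endpoint]
    mode = block["mode"]
    where = f"survival.{arm}.{endpoint}"
    if mode == "median":
        family = block.get("family", "exponential")
        median = block.get("median_months")
        if median is None:
            raise ConfigError(f"{where}.median_months", "missing")
        extra = block.get("sigma")
        return curve_from_median(family, float(median), extra).to_unit("days")
    criterion = block.get("criterion", "AIC")
    if mode == "ipd":
        if "csv" not in block:
            raise ConfigError(f"{where}.csv", "missing IPD path")
        data = IPDataset.from_csv(cfg.resolve_path(block["csv"]), endpoint.upper())
        if arm in data.arms:
            data = data.for_arm(arm)
    else:  # km
        if "csv" not in block:
            raise ConfigError(f"{where}.csv", "missing digitized-curve path")
        km = KMDigitized.from_csv(cfg.resolve_path(block["csv"]))
        data = reconstruct_ipd_from_km(
            km, n_initial=block.get("n_initial"), arm=arm, endpoint=endpoint.upper()
        )
    chosen = select_model(fit_all_families(data), criterion)
    return chosen.curve


def build_model(cfg: RunConfig) -> PSModel:
    """Resolve curves and assemble the two-strategy model."""
    plan_block = cfg.raw.get("cycle_plan", {})
    plan = build_cycle_plan(
        horizon_years=float(plan_block.get("horizon_years", 5)),
        cycle_length_days=float(plan_block.get("cycle_length_days", 21)),
        discount=float(plan_block.get("discount", 0.05)),
        evaluation=plan_block.get("evaluation", "midpoint"),
    )
    curves = {
        arm: ArmCurves(
            os_curve=_curve_from_block(cfg, arm, "os"),
            pfs_curve=_curve_from_block(cfg, arm, "pfs"),
        )
        for arm in cfg.raw["survival"]
    }
    bg = cfg.raw.get("background_mortality", {})
    life_table = None
    if bg.get("life_table_csv"):
        life_table = LifeTable.from_csv(cfg.resolve_path(bg["life_table_csv"]))
    caps_raw = cfg.raw.get("treatment_caps", {})
    caps = {
        arm: (None if caps_raw.get(arm) is None else int(caps_raw[arm]))
        for arm in cfg.raw["survival"]
    }
    model_config = ModelConfig(
        curves=curves,
        plan=plan,
        wtp=cfg.wtp,
        reference=cfg.reference,
        comparator=cfg.comparator,
        use_background_mortality=bool(bg.get("enabled", True)),
        life_table=life_table,
        start_age_years=float(bg.get("start_age_years", 50)),
        treatment_caps=caps,
    )
    return PSModel(model_config)
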