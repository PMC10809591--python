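"""Synthetic two-arm trial data with the structure the model assumes.

The cost-effectiveness analysis is driven by overall-survival (OS) and
progression-free-survival (PFS) curves of a two-arm oncology trial.  No
patient-level data are available for such trials; published Kaplan-Meier
figures are digitized instead.  This module generates individual patient
data (IPD) and digitized-KM-style inputs with a known ground truth, so the
fitting, reconstruction and economic stages can all be exercised end to end.

The default scenario emulates a pembrolizumab-versus-chemotherapy trial in
platinum-pretreated recurrent/metastatic nasopharyngeal carcinoma: OS is
approximately exponential with medians 17.2 / 15.3 months and PFS is
approximately lognormal with medians 4.1 / 5.5 months (sigma 1.0), under
uniform accrual and a fixed administrative cutoff.  Per-subject PFS never
exceeds OS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .curves import DAYS_PER_MONTH, ParametricCurve

__all__ = [
    "IPDataset",
    "KMDigitized",
    "CensoringSpec",
    "ArmSpec",
    "TrialScenario",
    "default_scenario",
    "simulate_arm_ipd",
    "simulate_trial",
    "km_estimate",
]


@dataclass(frozen=True)
class IPDataset:
    """Individual time-to-event records for one endpoint.

    ``frame`` has columns ``time_days`` (strictly positive), ``event``
    (1 = event, 0 = censored) and ``arm`` (strategy label).
    """

    frame: pd.DataFrame
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        required = {"time_days", "event", "arm"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"IPDataset frame missing columns {sorted(missing)}")
        t = self.frame["time_days"].to_numpy(dtype=float)
        e = self.frame["event"].to_numpy()
        if len(t) == 0:
            raise ValueError("IPDataset must contain at least one record")
        if np.any(t <= 0) or np.any(~np.isfinite(t)):
            raise ValueError("all times must be strictly positive and finite")
        if not np.all(np.isin(e, (0, 1))):
            raise ValueError("event indicator must be 0 or 1")

    @property
    def times(self) -> np.ndarray:
        return self.frame["time_days"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.frame["event"].to_numpy(dtype=int)

    @property
    def arms(self) -> list[str]:
        return sorted(self.frame["arm"].unique())

    def for_arm(self, arm: str) -> "IPDataset":
        sub = self.frame[self.frame["arm"] == arm].reset_index(drop=True)
        if len(sub) == 0:
            raise ValueError(f"no records for arm {arm!r}; have {self.arms}")
        return IPDataset(sub, self.endpoint)

    def n_events(self) -> int:
        return int(self.events.sum())

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["time_days"] = out["time_days"].map(lambda v: f"{v:.6f}")
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, endpoint: str = "OS") -> "IPDataset":
        return cls(pd.read_csv(path), endpoint)


@dataclass(frozen=True)
class KMDigitized:
    """Kaplan-Meier curve coordinates, as read off a published figure.

    ``times`` strictly increasing (days); ``survival`` non-increasing in
    [0, 1].  ``risk_times``/``n_risk`` optionally hold a numbers-at-risk
    table with non-increasing counts.
    """

    times: np.ndarray
    survival: np.ndarray
    risk_times: np.ndarray | None = None
    n_risk: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        if t.shape != s.shape or t.ndim != 1 or len(t) == 0:
            raise ValueError("times and survival must be equal-length 1-d arrays")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if s[0] > 1.0 + 1e-12 or np.any(s < -1e-12):
            raise ValueError("survival must lie in [0, 1]")
        if (self.risk_times is None) != (self.n_risk is None):
            raise ValueError("risk_times and n_risk must be given together")
        if self.n_risk is not None:
            rt = np.asarray(self.risk_times, dtype=float)
            nr = np.asarray(self.n_risk, dtype=int)
            object.__setattr__(self, "risk_times", rt)
            object.__setattr__(self, "n_risk", nr)
            if np.any(np.diff(rt) <= 0) or np.any(np.diff(nr) > 0) or np.any(nr < 0):
                raise ValueError(
                    "risk table needs increasing times and non-increasing counts >= 0"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_days": self.times, "survival": self.survival})

    def to_csv(self, path) -> None:
        out = self.to_frame()
        out["time_days"] = out["time_days"].map(lambda v: f"{v:.6f}")
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "KMDigitized":
        df = pd.read_csv(path)
        return cls(df["time_days"].to_numpy(), df["survival"].to_numpy())


@dataclass(frozen=True)
class CensoringSpec:
    """Uniform accrual over ``accrual_days`` plus an administrative cutoff.

    A subject entering at u ~ U(0, accrual_days) is censored at
    cutoff_days - u if still event-free.  No loss to follow-up.
    """

    accrual_days: float = 365.25
    cutoff_days: float = 1095.75

    def __post_init__(self) -> None:
        if self.cutoff_days <= 0:
            raise ValueError("cutoff must be positive: no follow-up is possible")
        if self.accrual_days < 0:
            raise ValueError("accrual window cannot be negative")
        if self.cutoff_days <= self.accrual_days:
            raise ValueError("cutoff must exceed the accrual window")


@dataclass(frozen=True)
class ArmSpec:
    os_curve: ParametricCurve
    pfs_curve: ParametricCurve


@dataclass(frozen=True)
class TrialScenario:
    arms: dict[str, ArmSpec]
    n_per_arm: int = 100
    censoring: CensoringSpec = field(default_factory=CensoringSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ValueError("need at least 2 subjects per arm")
        if not self.arms:
            raise ValueError("scenario needs at least one arm")


def default_scenario(
    n_per_arm: int = 100, pfs_sigma: float = 1.0, seed: int = 0
) -> TrialScenario:
    """The packaged two-arm fixture calibrated to the published medians."""

    def _arm(os_median_m: float, pfs_median_m: float) -> ArmSpec:
        return ArmSpec(
            os_curve=ParametricCurve(
                "exponential", (np.log(2.0) / (os_median_m * DAYS_PER_MONTH),)
            ),
            pfs_curve=ParametricCurve(
                "lognormal", (np.log(pfs_median_m * DAYS_PER_MONTH), pfs_sigma)
            ),
        )

    return TrialScenario(
        arms={
            "pembrolizumab": _arm(17.2, 4.1),
            "chemotherapy": _arm(15.3, 5.5),
        },
        n_per_arm=n_per_arm,
        seed=seed,
    )


def simulate_arm_ipd(
    family: str,
    params,
    n: int,
    censor: CensoringSpec | None = None,
    seed: int = 0,
    arm: str = "arm",
    endpoint: str = "OS",
) -> IPDataset:
    """Draw ``n`` right-censored records from one parametric family."""
    curve = ParametricCurve(family, tuple(np.atleast_1d(params)))
    rng = np.random.default_rng(seed)
    event_times = np.maximum(curve.rvs(n, rng), 1e-9)
    if censor is None:
        times, events = event_times, np.ones(n, dtype=int)
    else:
        entry = rng.uniform(0.0, censor.accrual_days, size=n)
        censor_times = censor.cutoff_days - entry
        events = (event_times <= censor_times).astype(int)
        times = np.minimum(event_times, censor_times)
    frame = pd.DataFrame({"time_days": times, "event": events, "arm": arm})
    return IPDataset(frame, endpoint)


def simulate_trial(scenario: TrialScenario) -> dict[str, IPDataset]:
    """Simulate paired OS and PFS records for every arm of a scenario.

    OS and latent progression times share one uniform draw per subject
    (comonotone frailty: subjects who die early also progress early) and
    PFS is the minimum of the two, so PFS <= OS holds record-by-record
    while both marginal medians match their calibrated curves.  Both
    endpoints share each subject's accrual entry, hence its censoring
    time.  Returns ``{"OS": ..., "PFS": ...}``, each covering all arms.
    """
    rng = np.random.default_rng(scenario.seed)
    cens = scenario.censoring
    frames: dict[str, list[pd.DataFrame]] = {"OS": [], "PFS": []}
    for arm_name in sorted(scenario.arms):
        spec = scenario.arms[arm_name]
        n = scenario.n_per_arm
        u = rng.uniform(size=n)
        t_os = np.maximum(spec.os_curve.to_unit("days").quantile(u), 1e-9)
        t_prog = np.maximum(spec.pfs_curve.to_unit("days").quantile(u), 1e-9)
        t_pfs = np.minimum(t_os, t_prog)
        entry = rng.uniform(0.0, cens.accrual_days, size=n)
        c = cens.cutoff_days - entry
        for name, t in (("OS", t_os), ("PFS", t_pfs)):
            frames[name].append(
                pd.DataFrame(
                    {
                        "time_days": np.minimum(t, c),
                        "event": (t <= c).astype(int),
                        "arm": arm_name,
                    }
                )
            )
    return {
        name: IPDataset(pd.concat(parts, ignore_index=True), endpoint=name)
        for name, parts in frames.items()
    }


def km_estimate(data: IPDataset, risk_grid=None) -> KMDigitized:
    """Product-limit (Kaplan-Meier) estimate of one arm's survival curve.

    The output uses the same coordinate format a figure digitizer would
    produce: the curve value just after each distinct observed time,
    preceded by the point (0, 1).  ``risk_grid`` requests a numbers-at-risk
    table at the given times (days).
    """
    if len(data.arms) > 1:
        raise ValueError(
            f"km_estimate expects a single arm; filter with for_arm() from {data.arms}"
        )
    if data.n_events() == 0:
        raise ValueError("cannot estimate a survival curve with zero events")
    kmf = KaplanMeierFitter()
    kmf.fit(data.times, data.events)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    if times[0] != 0.0:
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
    risk_times = n_risk = None
    if risk_grid is not None:
        risk_times = np.asarray(risk_grid, dtype=float)
        n_risk = np.array(
            [int((data.times >= g).sum()) for g in risk_times], dtype=int
        )
    return KMDigitized(times, surv, risk_times, n_risk)
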