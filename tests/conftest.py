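import numpy as np
import pytest

from psmcea import PSModel, build_cycle_plan, default_model_config
from psmcea.psm_engine import Trace


@pytest.fixture(scope="session")
def base_model() -> PSModel:
    """Base-case model calibrated from the published medians."""
    with pytest.warns(UserWarning, match="PFS curve exceeds OS"):
        return PSModel(default_model_config())


@pytest.fixture(scope="session")
def base_plan():
    return build_cycle_plan()


def make_trace(pfs, pd_, t_days=None, on_treatment=None) -> Trace:
    """Hand-build a trace from PFS/PD occupancy arrays."""
    pfs = np.asarray(pfs, dtype=float)
    pd_ = np.asarray(pd_, dtype=float)
    dead = 1.0 - pfs - pd_
    if t_days is None:
        t_days = (np.arange(1, len(pfs) + 1) - 0.5) * 21.0
    return Trace(
        t_days=np.asarray(t_days, dtype=float),
        pfs=pfs,
        pd=pd_,
        dead=dead,
        new_deaths=np.maximum(np.diff(dead, prepend=0.0), 0.0),
        on_treatment=pfs.copy() if on_treatment is None else np.asarray(on_treatment),
    )


def random_trace(rng: np.random.Generator, n_cycles: int = 87) -> Trace:
    """A random valid trace: monotone dead, PFS within the survivors."""
    dead = np.sort(rng.uniform(0, 1, size=n_cycles))
    alive = 1.0 - dead
    pfs = alive * np.sort(rng.uniform(0, 1, size=n_cycles))[::-1]
    return make_trace(pfs, alive - pfs)
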