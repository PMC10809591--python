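"""Cost/effect accrual arithmetic, ICER and NMB identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_trace
from psmcea.economics import (
    AEEvent,
    StrategyInputs,
    StrategyTotals,
    UtilityInputs,
    accrue_costs,
    accrue_effects,
    compute_icer,
    discount_factor,
    mixed_drug_cost,
    net_monetary_benefit,
)
from psmcea.psm_engine import build_cycle_plan

CHEMO_AES = (AEEvent("anemia", 0.107, 6562.68), AEEvent("neutrocytopenia", 0.277, 475.32))
PEMBRO_AES = (AEEvent("anemia", 0.009, 6562.68), AEEvent("neutrocytopenia", 0.0, 475.32))


def _plan(n_cycles, discount=0.0):
    return build_cycle_plan(
        horizon_years=n_cycles * 21.0 / 365.25, cycle_length_days=21.0, discount=discount
    )


class TestDiscountFactor:
    def test_one_year_at_five_percent(self):
        assert discount_factor(365.25, 0.05) == pytest.approx(1 / 1.05, abs=5e-7)

    def test_time_zero(self):
        assert discount_factor(0.0, 0.05) == 1.0

    def test_zero_rate(self):
        assert discount_factor(1234.5, 0.0) == 1.0

    def test_rate_below_minus_one_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(10.0, -1.5)


class TestAccrueCosts:
    def test_chemotherapy_ae_lump_sum(self):
        """Incidence-weighted AE cost: 0.107*6562.68 + 0.277*475.32."""
        trace = make_trace([0.0], [0.0], on_treatment=[0.0])
        inputs = StrategyInputs(
            "chemo", 0.0, CHEMO_AES, imaging_cost=0, lab_cost=0, terminal_care_cost=0
        )
        costs = accrue_costs(trace, inputs, _plan(1))
        assert costs.adverse_events == pytest.approx(833.87, abs=0.005)
        assert costs.total == pytest.approx(833.87, abs=0.005)

    def test_pembrolizumab_ae_lump_sum(self):
        trace = make_trace([0.0], [0.0], on_treatment=[0.0])
        inputs = StrategyInputs(
            "pembro", 0.0, PEMBRO_AES, imaging_cost=0, lab_cost=0, terminal_care_cost=0
        )
        costs = accrue_costs(trace, inputs, _plan(1))
        assert costs.adverse_events == pytest.approx(59.06, abs=0.005)

    def test_drug_cost_two_full_cycles(self):
        trace = make_trace([1.0, 1.0], [0.0, 0.0])
        inputs = StrategyInputs("pembro", 5327.90, (), imaging_cost=0, lab_cost=0)
        costs = accrue_costs(trace, inputs, _plan(2))
        # labs every cycle are disabled via lab_cost=0; no deaths occur
        assert costs.drug == pytest.approx(2 * 5327.90)

    def test_terminal_care_follows_new_deaths(self):
        trace = make_trace([1.0, 0.0], [0.0, 0.0])  # everyone dies in cycle 2
        inputs = StrategyInputs("x", 0.0, (), imaging_cost=0, lab_cost=0)
        costs = accrue_costs(trace, inputs, _plan(2))
        assert costs.terminal_care == pytest.approx(1460.30)

    def test_monitoring_schedule(self):
        """Labs every cycle, imaging every third cycle, while alive."""
        trace = make_trace([1.0] * 6, [0.0] * 6)
        inputs = StrategyInputs("x", 0.0, (), terminal_care_cost=0)
        costs = accrue_costs(trace, inputs, _plan(6))
        assert costs.laboratory == pytest.approx(6 * 11.89)
        assert costs.imaging == pytest.approx(2 * 207.25)

    def test_length_mismatch_rejected(self):
        trace = make_trace([1.0], [0.0])
        inputs = StrategyInputs("x", 0.0)
        with pytest.raises(ValueError, match="cycles"):
            accrue_costs(trace, inputs, _plan(2))

    def test_mixed_drug_cost(self):
        assert mixed_drug_cost(
            [36.39, 44.16, 31.22], [1 / 3, 1 / 3, 1 / 3]
        ) == pytest.approx(37.2567, abs=1e-4)
        with pytest.raises(ValueError):
            mixed_drug_cost([1.0, 2.0], [0.6, 0.6])


class TestAccrueEffects:
    def test_one_cycle_fully_pfs(self):
        trace = make_trace([1.0], [0.0])
        eff = accrue_effects(trace, UtilityInputs(), _plan(1))
        assert eff.ly == pytest.approx(21 / 365.25, abs=1e-6)
        assert eff.qaly == pytest.approx(0.76 * 21 / 365.25, abs=1e-6)

    def test_utilities_of_one_make_qaly_equal_ly(self):
        trace = make_trace([0.4, 0.2], [0.3, 0.3])
        eff = accrue_effects(trace, UtilityInputs(1.0, 1.0, 0.0), _plan(2, 0.05))
        assert eff.qaly == pytest.approx(eff.ly)

    def test_all_dead_trace_zero(self):
        trace = make_trace([0.0], [0.0])
        eff = accrue_effects(trace, UtilityInputs(), _plan(1))
        assert eff.ly == 0.0 and eff.qaly == 0.0

    def test_utility_ordering_enforced(self):
        with pytest.raises(ValueError):
            UtilityInputs(u_pfs=0.3, u_pd=0.5)


class TestICER:
    def test_self_comparison_is_null(self):
        a = StrategyTotals("a", 1000.0, 1.0, 0.8)
        res = compute_icer(a, a, 38223.34)
        assert res.incr_cost == 0.0 and res.incr_qaly == 0.0
        assert np.isnan(res.icer_per_qaly)
        assert res.dominance == "none"

    def test_dominance_classification(self):
        cheap_good = StrategyTotals("a", 500.0, 1.2, 1.0)
        dear_bad = StrategyTotals("b", 900.0, 1.0, 0.8)
        assert compute_icer(cheap_good, dear_bad, 1e4).dominance == "dominant"
        assert compute_icer(dear_bad, cheap_good, 1e4).dominance == "dominated"

    def test_equal_effects_dominated_by_cost(self):
        a = StrategyTotals("a", 900.0, 1.0, 0.8)
        b = StrategyTotals("b", 500.0, 1.0, 0.8)
        res = compute_icer(a, b, 1e4)
        assert np.isnan(res.icer_per_qaly)
        assert res.dominance == "dominated"

    def test_printed_totals_arithmetic(self):
        chemo = StrategyTotals("chemotherapy", 2734.55, 3.93, 2.73)
        pembro = StrategyTotals("pembrolizumab", 39710.96, 3.96, 2.82)
        res = compute_icer(pembro, chemo, 38223.34)
        assert res.incr_cost == pytest.approx(36976.41, abs=0.005)
        assert res.incr_qaly == pytest.approx(0.09, abs=1e-9)
        assert res.icer_per_ly == pytest.approx(1232547.00, abs=0.005)
        assert not res.cost_effective


class TestNMB:
    def test_zero_wtp_is_negative_cost(self):
        t = StrategyTotals("a", 1234.0, 1.0, 0.8)
        assert net_monetary_benefit(t, 0.0) == -1234.0

    def test_incremental_nmb_arithmetic(self):
        wtp = 38223.34
        a = StrategyTotals("a", 39710.96, 3.96, 2.8175)
        b = StrategyTotals("b", 2734.55, 3.93, 2.73)
        inmb = net_monetary_benefit(a, wtp) - net_monetary_benefit(b, wtp)
        assert inmb == pytest.approx(wtp * 0.0875 - 36976.41, abs=0.01)
        assert inmb < 0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        d_cost=st.floats(-1e5, 1e5),
        d_qaly=st.floats(0.001, 2.0),
        wtp=st.floats(0.0, 1e5),
    )
    def test_positive_inmb_iff_icer_below_wtp(self, d_cost, d_qaly, wtp):
        """With a QALY gain, iNMB > 0 exactly when the ICER is under WTP."""
        icer = d_cost / d_qaly
        if abs(wtp * d_qaly - d_cost) < 1e-6:  # ties are float-noise territory
            return
        b = StrategyTotals("b", 0.0, 1.0, 0.0)
        a = StrategyTotals("a", d_cost, 1.0, d_qaly)
        inmb = net_monetary_benefit(a, wtp) - net_monetary_benefit(b, wtp)
        assert (inmb > 0) == (icer < wtp)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    u_pfs=st.floats(0.4, 1.0),
    u_pd=st.floats(0.0, 0.4),
    scale=st.floats(1.0, 3.0),
)
def test_monotonicity_properties(u_pfs, u_pd, scale):
    """Higher unit costs raise costs; higher utilities raise QALYs; QALY<=LY."""
    trace = make_trace([0.5, 0.3, 0.2], [0.2, 0.3, 0.3])
    plan = _plan(3, 0.05)
    base_inputs = StrategyInputs("x", 100.0, CHEMO_AES)
    scaled = StrategyInputs(
        "x", 100.0 * scale, CHEMO_AES,
        imaging_cost=207.25 * scale, lab_cost=11.89 * scale,
        terminal_care_cost=1460.30 * scale,
    )
    assert accrue_costs(trace, scaled, plan).total >= accrue_costs(trace, base_inputs, plan).total
    eff = accrue_effects(trace, UtilityInputs(u_pfs, u_pd), plan)
    eff_hi = accrue_effects(trace, UtilityInputs(min(u_pfs + 0.1, 1.0), u_pd), plan)
    assert eff_hi.qaly >= eff.qaly
    assert eff.qaly <= eff.ly + 1e-12
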