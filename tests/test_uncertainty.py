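"""Sensitivity analysis: tornado, moment-matched sampling, PSA, CEAC."""

import numpy as np
import pytest

from psmcea.uncertainty import (
    ParamSpec,
    ce_plane,
    ceac,
    default_param_specs,
    moment_matched_distribution,
    one_way_dsa,
    run_psa,
)

WTP = 38223.34


class TestMomentMatching:
    def test_gamma_moments(self):
        """Anemia-cost gamma: sampled mean/SD within 2% at 10,000 draws."""
        spec = ParamSpec("anemia_cost", 6562.68, 5250.14, 7875.22, "gamma")
        draws = moment_matched_distribution(spec).rvs(10_000, np.random.default_rng(1))
        assert draws.mean() == pytest.approx(6562.68, rel=0.02)
        assert draws.std() == pytest.approx((7875.22 - 5250.14) / 3.92, rel=0.02)
        assert np.all(draws > 0)

    def test_beta_moments_and_support(self):
        spec = ParamSpec("utility_pfs", 0.76, 0.61, 0.91, "beta")
        draws = moment_matched_distribution(spec).rvs(10_000, np.random.default_rng(2))
        assert draws.mean() == pytest.approx(0.76, rel=0.02)
        assert draws.std() == pytest.approx(0.30 / 3.92, rel=0.02)
        assert np.all((draws > 0) & (draws < 1))

    def test_zero_spread_is_point_mass(self):
        spec = ParamSpec("x", 5.0, 5.0, 5.0, "gamma")
        draws = moment_matched_distribution(spec).rvs(100, np.random.default_rng(3))
        assert np.all(draws == 5.0)

    def test_beta_base_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            ParamSpec("bad", 1.5, 1.0, 2.0, "beta")

    def test_infeasible_beta_moments_named(self):
        spec = ParamSpec("nearly_degenerate", 0.5, -10.0, 11.0, "beta")
        with pytest.raises(ValueError, match="nearly_degenerate"):
            moment_matched_distribution(spec)

    def test_ordering_constraint_on_spec(self):
        with pytest.raises(ValueError):
            ParamSpec("x", 1.0, 2.0, 0.5)

    def test_pm20_rule(self):
        spec = ParamSpec.pm20("p_anemia_chemotherapy", 0.107, "beta")
        assert spec.low == pytest.approx(0.0856)
        assert spec.high == pytest.approx(0.1284)


class TestOneWayDSA:
    def test_spans_match_brute_force(self, base_model):
        """Every tornado row equals a from-scratch model run at its bounds."""
        specs = default_param_specs()[:5]
        table = one_way_dsa(base_model, specs, WTP)
        for spec in specs:
            row = table[table["parameter"] == spec.name].iloc[0]
            lo = base_model.evaluate({spec.name: spec.low}).icer_per_qaly
            hi = base_model.evaluate({spec.name: spec.high}).icer_per_qaly
            assert row["icer_low"] == pytest.approx(lo, rel=1e-12)
            assert row["icer_high"] == pytest.approx(hi, rel=1e-12)
            assert row["span"] == pytest.approx(abs(hi - lo), rel=1e-12)

    def test_degenerate_range_zero_span(self, base_model):
        spec = ParamSpec("lab_cost", 11.89, 11.89, 11.89)
        table = one_way_dsa(base_model, [spec], WTP)
        assert table["span"].iloc[0] == 0.0

    def test_sorted_and_order_invariant(self, base_model):
        specs = default_param_specs()[:6]
        t1 = one_way_dsa(base_model, specs, WTP)
        t2 = one_way_dsa(base_model, list(reversed(specs)), WTP)
        assert np.all(np.diff(t1["span"].to_numpy()) <= 1e-9)
        assert list(t1["parameter"]) == list(t2["parameter"])
        assert np.all(t1["span"].to_numpy() >= 0)

    def test_unknown_parameter_rejected(self, base_model):
        with pytest.raises(KeyError):
            one_way_dsa(base_model, [ParamSpec("nope", 1.0, 0.5, 1.5)], WTP)


class TestPSA:
    @pytest.fixture(scope="class")
    def results(self, base_model):
        return run_psa(base_model, default_param_specs(), n_iter=300, seed=12)

    def test_seed_determinism(self, base_model):
        specs = default_param_specs()
        r1 = run_psa(base_model, specs, n_iter=50, seed=5)
        r2 = run_psa(base_model, specs, n_iter=50, seed=5)
        assert r1.outcomes.equals(r2.outcomes)
        assert r1.draws.equals(r2.draws)

    def test_all_fixed_specs_reproduce_base_case(self, base_model):
        specs = [
            ParamSpec("lab_cost", 11.89, 11.89, 11.89, "fixed"),
            ParamSpec("utility_pfs", 0.76, 0.76, 0.76, "fixed"),
        ]
        res = run_psa(base_model, specs, n_iter=5, seed=1)
        base = base_model.evaluate()
        assert np.allclose(res.outcomes["incr_cost"], base.incr_cost)
        assert np.allclose(res.outcomes["incr_qaly"], base.incr_qaly)

    def test_mean_incremental_cost_near_base(self, results, base_model):
        """Costs are sampled with mean = base, so PSA means track base case."""
        base = base_model.evaluate()
        assert results.outcomes["incr_cost"].mean() == pytest.approx(
            base.incr_cost, rel=0.05
        )

    def test_no_missing_values(self, results):
        assert not results.outcomes.isna().any().any()
        assert len(results.outcomes) == 300


class TestCEAC:
    def test_probabilities_match_direct_count(self, base_model):
        results = run_psa(base_model, default_param_specs(), n_iter=200, seed=7)
        grid = [0.0, WTP, 10 * WTP]
        curve = ceac(results, grid)
        assert np.all((curve["probability"] >= 0) & (curve["probability"] <= 1))
        dq = results.outcomes["incr_qaly"].to_numpy()
        dc = results.outcomes["incr_cost"].to_numpy()
        for w, p in zip(curve["wtp"], curve["probability"]):
            count = sum(
                1
                for q, c in zip(dq, dc)
                if (q > 0 and c / q < w) or (q < 0 and c / q > w and c < 0) or (c < 0 and q >= 0)
            )
            # direct per-iteration classification of cost-effectiveness
            assert p == pytest.approx(count / len(dq), abs=1e-12)

    def test_wtp_zero_counts_cheaper_draws(self, base_model):
        results = run_psa(base_model, default_param_specs(), n_iter=200, seed=8)
        p0 = ceac(results, [0.0])["probability"].iloc[0]
        frac_cheaper = (results.outcomes["incr_cost"] < 0).mean()
        assert p0 == pytest.approx(frac_cheaper, abs=1e-12)
        assert p0 == 0.0

    def test_dominant_every_draw_gives_probability_one(self, base_model):
        import pandas as pd

        from psmcea.uncertainty import PSAResults

        outcomes = pd.DataFrame(
            {
                "cost_reference": [1.0, 2.0],
                "qaly_reference": [2.0, 2.0],
                "cost_comparator": [5.0, 6.0],
                "qaly_comparator": [1.0, 1.0],
                "incr_cost": [-4.0, -4.0],
                "incr_qaly": [1.0, 1.0],
            }
        )
        res = PSAResults(outcomes[["incr_cost"]], outcomes, 2, 0)
        curve = ceac(res, [0.0, 1.0, 1e6])
        assert np.all(curve["probability"] == 1.0)

    def test_empty_grid_rejected(self, base_model):
        results = run_psa(base_model, default_param_specs()[:2], n_iter=5, seed=1)
        with pytest.raises(ValueError):
            ceac(results, [])


class TestCEPlane:
    def test_point_count_and_quadrants(self, base_model):
        results = run_psa(base_model, default_param_specs(), n_iter=150, seed=4)
        plane = ce_plane(results)
        assert len(plane) == 150
        q = (
            ((plane["incr_qaly"] >= 0) & (plane["incr_cost"] >= 0)).sum()
            + ((plane["incr_qaly"] >= 0) & (plane["incr_cost"] < 0)).sum()
            + ((plane["incr_qaly"] < 0) & (plane["incr_cost"] >= 0)).sum()
            + ((plane["incr_qaly"] < 0) & (plane["incr_cost"] < 0)).sum()
        )
        assert q == 150

    def test_upper_half_plane_dominates(self, base_model):
        """The reference drug carries a ~$40k premium in essentially every draw."""
        results = run_psa(base_model, default_param_specs(), n_iter=300, seed=13)
        frac_upper = (results.outcomes["incr_cost"] > 0).mean()
        assert frac_upper >= 0.99
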