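"""PSA draws, summaries, acceptability curves and the one-way tornado."""

import math

import numpy as np
import pandas as pd
import pytest

from asthma_cua import (
    ScenarioSpec,
    ceac,
    load_parameter_set,
    one_way_dsa,
    run_psa,
    summarize_psa,
)
from asthma_cua.params import ParameterError, build_sampling_plan
from asthma_cua.psa import evaluate_strategies


def draws_frame(pairs, wtp=10.0):
    """Build a minimal draw table from (dc, de) pairs."""
    dc = np.array([p[0] for p in pairs], dtype=float)
    de = np.array([p[1] for p in pairs], dtype=float)
    return pd.DataFrame({
        "draw": np.arange(len(pairs)),
        "cost_comparator": np.zeros(len(pairs)),
        "qaly_comparator": np.zeros(len(pairs)),
        "cost_addon": dc,
        "qaly_addon": de,
        "dc": dc,
        "de": de,
        "nmb_inc": de * wtp - dc,
    })


@pytest.fixture(scope="module")
def small_psa(params, life_table):
    return run_psa(params, ScenarioSpec(horizon=40), life_table,
                   n_runs=400, seed=11)


# conftest fixtures are function/session scoped; re-expose for module scope
@pytest.fixture(scope="module")
def params():
    from asthma_cua import table1_fixture

    return table1_fixture()


@pytest.fixture(scope="module")
def life_table():
    from asthma_cua import synthetic_life_table

    return synthetic_life_table()


class TestRunPsa:
    def test_reproducible_from_seed(self, params, life_table):
        scenario = ScenarioSpec(horizon=30)
        a = run_psa(params, scenario, life_table, n_runs=50, seed=5)
        b = run_psa(params, scenario, life_table, n_runs=50, seed=5)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_degenerate_ranges_reproduce_base_case(self, params, life_table):
        collapsed = {}
        for item in build_sampling_plan(params):
            section, name = item.path.split(".")
            base = params.point(item.path).base
            collapsed.setdefault(section, {})[name] = {"base": base, "lower": base,
                                                       "upper": base}
        degenerate = load_parameter_set(collapsed)
        scenario = ScenarioSpec(horizon=30)
        psa = run_psa(degenerate, scenario, life_table, n_runs=5, seed=1)
        comp, addon = evaluate_strategies(degenerate, scenario, life_table)
        assert (psa.draws.cost_comparator == comp.discounted_cost).all()
        assert (psa.draws.qaly_addon == addon.discounted_qaly).all()

    def test_sampled_rr_mean_near_base(self, params, life_table):
        psa = run_psa(params, ScenarioSpec(horizon=2), life_table,
                      n_runs=2000, seed=3)
        rr = psa.draws.par_effect_rr_exacerbation
        (item,) = [p for p in build_sampling_plan(params)
                   if p.path == "effect.rr_exacerbation"]
        se = item.dist.sd() / math.sqrt(len(rr))
        assert abs(rr.mean() - 0.72) < 3 * se

    def test_common_random_parameters(self, small_psa):
        """Each draw applies one sampled set to both strategies."""
        d = small_psa.draws
        np.testing.assert_allclose(d.dc, d.cost_addon - d.cost_comparator,
                                   atol=1e-12)
        np.testing.assert_allclose(d.de, d.qaly_addon - d.qaly_comparator,
                                   atol=1e-12)

    def test_invalid_run_count(self, params, life_table):
        with pytest.raises(ParameterError):
            run_psa(params, ScenarioSpec(horizon=5), life_table, n_runs=0)


class TestSummarizePsa:
    def test_identical_dominant_draws(self):
        frame = draws_frame([(-1.0, 0.1)] * 5)
        s = summarize_psa(frame, wtp=10.0)
        assert s.p_cost_saving == 1.0
        assert s.p_more_effective == 1.0
        assert s.p_cost_effective == 1.0
        assert s.icer_of_means.quadrant.startswith("dominant")

    def test_symmetric_costs_give_half_probability(self):
        rng = np.random.default_rng(8)
        dc = rng.normal(0.0, 1.0, 4000)
        frame = draws_frame(list(zip(dc, np.full(4000, 0.01))))
        s = summarize_psa(frame, wtp=10.0)
        assert s.p_cost_saving == pytest.approx(0.5, abs=0.03)

    def test_two_point_enumeration(self):
        # draws {(-1, 0.1), (1, -0.1)} at λ=10: NMB = {2, -2} -> P = 0.5
        s = summarize_psa(draws_frame([(-1.0, 0.1), (1.0, -0.1)]), wtp=10.0)
        assert s.p_cost_effective == 0.5
        assert s.p_cost_saving == 0.5
        assert s.p_more_effective == 0.5

    def test_expected_nmb_is_linear_in_means(self, small_psa):
        s = small_psa.summary()
        for k in ("comparator", "add_on"):
            assert abs(s.expected_nmb[k]
                       - (s.mean_qaly[k] * s.wtp - s.mean_cost[k])) < 1e-9

    def test_centiles_ordered(self, small_psa):
        s = small_psa.summary()
        assert s.ci_delta_cost[0] <= s.ci_delta_cost[1]
        assert s.ci_delta_qaly[0] <= s.ci_delta_qaly[1]
        assert s.ci_nmb["add_on"][0] <= s.ci_nmb["add_on"][1]


class TestCeac:
    def test_endpoint_identities(self, small_psa):
        d = small_psa.draws
        curve = ceac(small_psa, [0.0, 1e9])
        assert curve.probability[0] == np.mean(d.dc < 0)
        assert curve.probability[1] == np.mean(d.de > 0)

    def test_all_dominant_draws_curve_is_one(self):
        frame = draws_frame([(-1.0, 0.1)] * 7)
        curve = ceac(frame, np.linspace(0, 100, 11))
        assert (curve.probability == 1.0).all()

    def test_four_draw_enumeration(self):
        frame = draws_frame([(-2.0, 0.0), (1.0, 0.5), (3.0, 0.1), (-1.0, -0.2)])
        curve = ceac(frame, [0.0, 10.0, 40.0])
        # λ=0: dc<0 in draws 1 and 4 -> 0.5
        # λ=10: nmb = {2, 4, -2, -1} -> 0.5
        # λ=40: nmb = {2, 19, 1, -7} -> 0.75
        np.testing.assert_array_equal(curve.probability, [0.5, 0.5, 0.75])

    def test_matches_summary_at_wtp(self, small_psa):
        s = small_psa.summary()
        assert ceac(small_psa, [s.wtp]).probability[0] == s.p_cost_effective

    def test_negative_grid_rejected(self, small_psa):
        with pytest.raises(ParameterError):
            ceac(small_psa, [-1.0])


@pytest.fixture(scope="module")
def dsa(params, life_table):
    return one_way_dsa(params, ScenarioSpec(horizon=40), life_table)


class TestOneWayDsa:
    def test_zero_width_for_degenerate_parameter(self, params, life_table):
        p = load_parameter_set({"utilities": {"decrement_ocs":
                                              {"base": 0.1, "lower": 0.1,
                                               "upper": 0.1}}})
        dsa = one_way_dsa(p, ScenarioSpec(horizon=40), life_table,
                          parameters=("utilities.decrement_ocs",))
        assert dsa.table.width.iloc[0] == 0.0

    def test_base_identity(self, params, life_table, dsa):
        """All parameters at base reproduces the base incremental result."""
        scenario = ScenarioSpec(horizon=40)
        comp, addon = evaluate_strategies(params, scenario, life_table)
        from asthma_cua.outcomes import IncrementalResult

        inc = IncrementalResult.from_strategies(comp, addon,
                                                params.econ.wtp_per_qaly)
        assert dsa.base.incremental_nmb == pytest.approx(inc.incremental_nmb,
                                                         rel=1e-12)

    def test_tornado_sorted_by_width(self, dsa):
        widths = dsa.table.width.to_numpy()
        assert (np.diff(widths) <= 1e-12).all()
        assert set(dsa.table.parameter) >= {"costs.drug_per_4wk",
                                            "effect.rr_exacerbation"}

    def test_drug_cost_bar_matches_direct_recomputation(self, params, life_table,
                                                        dsa):
        """The drug-cost NMB span equals the discounted drug-exposure-weighted
        unit-cost difference computed directly from the trace."""
        from asthma_cua.engine import run_cohort
        from asthma_cua.outcomes import discount_factor, half_cycle_weights

        scenario = ScenarioSpec(horizon=40)
        trace = run_cohort(params, "add_on", scenario, life_table)
        w = half_cycle_weights(len(trace.cycle))
        df = discount_factor(trace.cycle, params.econ.annual_discount_rate.base,
                             params.econ.cycle_days)
        exposure = np.sum(w * df * trace.frac_on_treatment * trace.alive)
        pr = params.costs.drug_per_4wk
        expected_span = exposure * (pr.upper - pr.lower) / 2.0  # per-cycle = per-4wk/2
        row = dsa.table.set_index("parameter").loc["costs.drug_per_4wk"]
        assert abs(row.nmb_low - row.nmb_high) == pytest.approx(expected_span,
                                                                rel=1e-9)
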