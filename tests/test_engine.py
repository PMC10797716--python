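"""Cohort propagation: conversions, transitions, adherence blending, oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asthma_cua import (
    ScenarioSpec,
    apply_relative_risk,
    blend_adherence,
    build_cycle_transition,
    load_parameter_set,
    oracle_simulate,
    rate_to_cycle_probability,
    run_cohort,
    synthetic_life_table,
)
from asthma_cua.engine import _event_probabilities, normalize_strategy
from asthma_cua.params import ParameterError


class TestConversions:
    def test_rate_to_cycle_probability(self):
        assert rate_to_cycle_probability(0.0, 14) == 0.0
        # 1 - exp(-1.14*14/365.25)
        assert rate_to_cycle_probability(1.14, 14) == pytest.approx(0.042755, rel=1e-4)
        assert rate_to_cycle_probability(1e9, 14) == pytest.approx(1.0)

    @given(rates=st.tuples(st.floats(0, 50), st.floats(0, 50)))
    def test_rate_conversion_monotone(self, rates):
        lo, hi = sorted(rates)
        assert rate_to_cycle_probability(lo, 14) <= rate_to_cycle_probability(hi, 14)

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            rate_to_cycle_probability(-0.1, 14)

    @pytest.mark.parametrize(
        "rate, rr, expected",
        [(1.14, 0.72, 0.8208), (3.3, 1.0, 3.3), (0.0, 0.5, 0.0)],
    )
    def test_apply_relative_risk(self, rate, rr, expected):
        assert apply_relative_risk(rate, rr) == pytest.approx(expected, rel=1e-12)

    def test_strategy_aliases(self):
        assert normalize_strategy("Tiotropium") == "add_on"
        assert normalize_strategy("ICS+LABA") == "comparator"
        with pytest.raises(ParameterError):
            normalize_strategy("placebo")


class TestCycleTransition:
    def test_base_case_hospitalization_probability(self, params, life_table):
        # 1 - exp(-0.25*1.14*0.72*14/365.25) with the default split
        tr = build_cycle_transition(params, True, 40.0, life_table)
        assert tr.p_event_hosp == pytest.approx(0.0078344, rel=1e-4)
        assert tr.p_death_asthma == 0.01

    def test_rr_one_makes_treatment_irrelevant(self, params, life_table):
        p = load_parameter_set({"effect": {"rr_exacerbation":
                                           {"base": 1.0, "lower": 1.0, "upper": 1.0}}})
        on = build_cycle_transition(p, True, 40.0, life_table)
        off = build_cycle_transition(p, False, 40.0, life_table)
        assert on == off

    def test_single_channel_split(self, life_table):
        p = load_parameter_set({"events": {"split_ocs": 1.0, "split_ed": 0.0,
                                           "split_hosp": 0.0}})
        tr = build_cycle_transition(p, False, 30.0, life_table)
        assert tr.p_event_ed == 0.0 and tr.p_event_hosp == 0.0
        assert tr.p_event_ocs > 0.0

    def test_oversized_probabilities_normalized(self, life_table):
        p = load_parameter_set({"events": {"exacerbation_annual_rate":
                                           {"base": 500.0, "lower": 500.0,
                                            "upper": 500.0}}})
        probs = _event_probabilities(p, on_treatment=False)
        assert probs.sum() <= 1.0 + 1e-12


class TestRunCohort:
    def test_conservation_and_absorption(self, params, scenario, life_table):
        for strategy in ("comparator", "add_on"):
            trace = run_cohort(params, strategy, scenario, life_table)
            np.testing.assert_allclose(trace.alive + trace.dead, 1.0, atol=1e-12)
            assert (np.diff(trace.dead) >= -1e-15).all()
            assert (trace.alive >= 0).all()

    def test_no_death_keeps_cohort_alive(self, params, short_scenario):
        immortal = synthetic_life_table(a=0.0, b=1e-15, c=0.0)
        p = load_parameter_set({"events": {"asthma_case_fatality_hosp": 0.0}})
        trace = run_cohort(p, "comparator", short_scenario, immortal)
        np.testing.assert_allclose(trace.alive, 1.0, atol=1e-12)

    def test_certain_death_absorbs_in_one_cycle(self, params, short_scenario):
        lethal = synthetic_life_table(a=50.0, b=1e-10, c=0.0)
        trace = run_cohort(params, "comparator", short_scenario, lethal)
        assert trace.alive[0] == 1.0
        assert trace.alive[-1] < 1e-6

    def test_add_on_reduces_exacerbations_before_waning(self, params, scenario,
                                                        life_table):
        comp = run_cohort(params, "comparator", scenario, life_table)
        addon = run_cohort(params, "add_on", scenario, life_table)
        wc = params.adherence.waning_cycle
        for name in ("inc_ocs", "inc_ed", "inc_hosp"):
            a, c = getattr(addon, name), getattr(comp, name)
            assert (a[:wc] < c[:wc]).all(), name
            n = min(len(a), len(c))
            assert (np.cumsum(a[:n]) <= np.cumsum(c[:n]) + 1e-12).all(), name

    def test_horizon_limits_trace_length(self, params, life_table):
        trace = run_cohort(params, "comparator", ScenarioSpec(horizon=30), life_table)
        assert trace.n_cycles <= 30

    def test_trace_csv_round_trip(self, params, short_scenario, life_table, tmp_path):
        trace = run_cohort(params, "add_on", short_scenario, life_table)
        path = tmp_path / "trace.csv"
        trace.write_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == ["cycle", "age", "alive", "dead", "inc_ocs",
                                    "inc_ed", "inc_hosp", "frac_on_treatment"]
        np.testing.assert_allclose(df.alive.to_numpy(), trace.alive)


class TestAdherenceBlending:
    def _sub_traces(self, params, scenario, life_table, fraction):
        override = {"adherence": {"discontinuation_fraction":
                                  {"base": fraction, "lower": 0.0, "upper": 1.0}}}
        p = load_parameter_set(override)
        full = load_parameter_set({"adherence": {"discontinuation_fraction":
                                                 {"base": 0.0, "lower": 0.0,
                                                  "upper": 1.0}}})
        none = load_parameter_set({"adherence": {"discontinuation_fraction":
                                                 {"base": 1.0, "lower": 0.0,
                                                  "upper": 1.0}}})
        return (run_cohort(p, "add_on", scenario, life_table),
                run_cohort(full, "add_on", scenario, life_table),
                run_cohort(none, "add_on", scenario, life_table))

    def test_zero_discontinuation_is_fully_adherent(self, params, short_scenario,
                                                    life_table):
        blended, adherent, _ = self._sub_traces(params, short_scenario, life_table, 0.0)
        np.testing.assert_array_equal(blended.alive, adherent.alive)
        np.testing.assert_array_equal(blended.inc_hosp, adherent.inc_hosp)

    def test_full_discontinuation_reverts_after_waning(self, params, short_scenario,
                                                       life_table):
        blended, _, reverted = self._sub_traces(params, short_scenario, life_table, 1.0)
        comp = run_cohort(load_parameter_set({}), "comparator", short_scenario,
                          life_table)
        wc = params.adherence.waning_cycle
        np.testing.assert_array_equal(blended.inc_ocs, reverted.inc_ocs)
        # after waning the reverted cohort uses comparator event probabilities
        ratio = blended.inc_ocs[wc:-1] / blended.alive[wc:-1]
        comp_ratio = comp.inc_ocs[wc:-1] / comp.alive[wc:-1]
        np.testing.assert_allclose(ratio, comp_ratio, rtol=1e-12)
        assert (blended.frac_on_treatment[:wc] == 1.0).all()
        assert (blended.frac_on_treatment[wc:] == 0.0).all()

    def test_mixture_matches_separate_sub_cohorts(self, params, short_scenario,
                                                  life_table):
        """Blended incidence is 0.72*adherent + 0.28*reverted, cycle by cycle."""
        blended, adherent, reverted = self._sub_traces(
            params, short_scenario, life_table, 0.28
        )
        for name in ("alive", "inc_ocs", "inc_ed", "inc_hosp"):
            a = getattr(adherent, name)
            r = getattr(reverted, name)
            np.testing.assert_allclose(
                getattr(blended, name), a + 0.28 * (r - a), rtol=0, atol=1e-15
            )

    def test_blend_adherence_function_matches_engine(self, params, short_scenario,
                                                     life_table):
        blended, adherent, reverted = self._sub_traces(
            params, short_scenario, life_table, 0.28
        )
        manual = blend_adherence(adherent, reverted, params.adherence)
        np.testing.assert_allclose(manual.alive, blended.alive, atol=1e-15)
        np.testing.assert_allclose(manual.frac_on_treatment,
                                   blended.frac_on_treatment, atol=1e-12)

    def test_invalid_fraction_rejected(self, params, short_scenario, life_table):
        adherent = run_cohort(params, "add_on", short_scenario, life_table)
        from dataclasses import replace

        from asthma_cua.params import PointRange

        bad = replace(params.adherence,
                      discontinuation_fraction=PointRange(1.5, 1.5, 1.5))
        with pytest.raises(ParameterError):
            blend_adherence(adherent, adherent, bad)


class TestOracleEquivalence:
    def test_deterministic_probabilities_agree_exactly(self, params, rng):
        immortal = synthetic_life_table(a=0.0, b=1e-15, c=0.0)
        p = load_parameter_set({
            "events": {"exacerbation_annual_rate": {"base": 0.0, "lower": 0.0,
                                                    "upper": 0.0},
                       "asthma_case_fatality_hosp": 0.0},
        })
        scenario = ScenarioSpec(horizon=20)
        engine = run_cohort(p, "comparator", scenario, immortal)
        oracle = oracle_simulate(p, "comparator", scenario, immortal, 500, rng)
        np.testing.assert_allclose(oracle.alive[:len(engine.alive)],
                                   engine.alive, atol=0)

    def test_seeded_reproducibility(self, params, short_scenario, life_table):
        a = oracle_simulate(params, "add_on", short_scenario, life_table, 2000,
                            np.random.default_rng(3))
        b = oracle_simulate(params, "add_on", short_scenario, life_table, 2000,
                            np.random.default_rng(3))
        np.testing.assert_array_equal(a.alive, b.alive)
        np.testing.assert_array_equal(a.inc_ed, b.inc_ed)

    def test_monte_carlo_agreement_quick(self, params, short_scenario, life_table,
                                         rng):
        """Empirical occupancy and incidence stay within 4 binomial SE."""
        n = 20_000
        engine = run_cohort(params, "add_on", short_scenario, life_table)
        oracle = oracle_simulate(params, "add_on", short_scenario, life_table, n, rng)
        m = min(len(engine.alive), len(oracle.alive))
        for name in ("alive", "inc_ocs", "inc_ed", "inc_hosp"):
            e = getattr(engine, name)[:m]
            o = getattr(oracle, name)[:m]
            se = np.sqrt(np.clip(e * (1 - e), 0, None) / n)
            assert (np.abs(o - e) <= 4 * se + 1e-12).all(), name
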