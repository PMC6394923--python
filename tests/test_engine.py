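"""Markov trace, decision-tree construction and expected-value rollup."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pdacpath import engine
from pdacpath.engine import (
    MarkovSpec,
    build_decision_tree,
    build_strategy_tree,
    calibrate_median,
    cohort_table,
    expected_value_rollup,
    median_to_hazard,
    run_cohort_trace,
    truncated_mean,
)
from pdacpath.parameters import HealthPhase, UtilityTable

FLAT_UTILS = UtilityTable({p: 1.0 for p in HealthPhase})


class TestHazards:
    def test_median_ln2_gives_unit_hazard(self):
        assert median_to_hazard(math.log(2.0)) == pytest.approx(1.0)

    def test_worked_value(self):
        assert median_to_hazard(6.931) == pytest.approx(0.1000, abs=2e-5)

    @given(st.floats(min_value=0.1, max_value=1000.0))
    def test_monthly_death_probability_in_unit_interval(self, median):
        q = 1.0 - math.exp(-median_to_hazard(median))
        assert 0.0 < q < 1.0

    def test_nonpositive_median_rejected(self):
        with pytest.raises(ValueError):
            median_to_hazard(0.0)


class TestTruncatedMean:
    def test_matches_closed_form_within_half_cycle(self):
        lam = math.log(2.0) / 12.0
        closed = (1.0 / lam) * (1.0 - math.exp(-60 * lam))
        assert abs(truncated_mean(lam, 60) - closed) <= 0.5

    def test_huge_hazard_limits_to_zero(self):
        assert truncated_mean(50.0, 60) == pytest.approx(0.0, abs=1e-12)

    def test_tiny_hazard_limits_to_horizon(self):
        assert truncated_mean(1e-9, 60) == pytest.approx(60.0, abs=1e-5)


class TestCalibrateMedian:
    @pytest.mark.parametrize("target", [10.86, 23.72, 35.05])
    def test_round_trip_through_trace(self, target):
        med = calibrate_median(target, 60)
        assert truncated_mean(median_to_hazard(med), 60) == pytest.approx(target, abs=1e-6)

    def test_near_horizon_target_converges(self):
        med = calibrate_median(59.99, 60)
        assert truncated_mean(median_to_hazard(med), 60) == pytest.approx(59.99, abs=1e-4)
        assert med > 1000

    def test_mean_monotone_in_median(self):
        medians = np.linspace(1.0, 50.0, 25)
        means = [truncated_mean(median_to_hazard(m), 60) for m in medians]
        assert np.all(np.diff(means) > 0)

    def test_infeasible_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate_median(60.0, 60)


class TestCohortTrace:
    def _spec(self, median=12.0, schedule=((HealthPhase.STABLE_DISEASE, None),)):
        return MarkovSpec(hazard=median_to_hazard(median), horizon=60, schedule=schedule)

    def test_occupancy_conserved_and_dead_monotone(self):
        trace = run_cohort_trace(self._spec(), FLAT_UTILS)
        sums = trace.occupancy.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert np.all(np.diff(trace.occupancy[:, 2]) >= -1e-12)

    def test_unit_utilities_make_qalm_equal_lm(self):
        trace = run_cohort_trace(self._spec(), FLAT_UTILS)
        assert trace.qalms == pytest.approx(trace.life_months, abs=1e-12)

    def test_unresectable_cohort_uses_flat_low_utility(self, baseline_inputs):
        # a 10.86-month cohort at utility 0.65 accrues 0.65 * 10.86 ~ 7.06 QALMs
        med = calibrate_median(10.86, 60)
        spec = MarkovSpec(
            hazard=median_to_hazard(med),
            horizon=60,
            schedule=((HealthPhase.UNRESECTABLE, None),),
            initial_state="alive_with_disease",
        )
        trace = run_cohort_trace(spec, baseline_inputs.utilities)
        assert trace.life_months == pytest.approx(10.86, abs=1e-6)
        assert trace.qalms == pytest.approx(0.65 * 10.86, abs=1e-6)
        assert trace.qalms == pytest.approx(7.06, abs=0.01)

    def test_qalm_increment_never_exceeds_lm_increment(self, baseline_inputs):
        sched = (
            (HealthPhase.ON_CHEMORADIOTHERAPY, 3),
            (HealthPhase.SURGICAL_COMPLICATION, 1),
            (HealthPhase.STABLE_DISEASE, None),
        )
        trace = run_cohort_trace(self._spec(schedule=sched), baseline_inputs.utilities)
        assert trace.qalms <= trace.life_months

    def test_huge_hazard_leaves_first_cycle_only(self):
        trace = run_cohort_trace(MarkovSpec(hazard=20.0, horizon=60), FLAT_UTILS)
        assert trace.life_months == pytest.approx(math.exp(-20.0), rel=1e-6)

    def test_progression_moves_between_alive_states(self):
        spec = MarkovSpec(hazard=0.01, horizon=24, progression_hazard=0.2)
        trace = run_cohort_trace(spec, FLAT_UTILS)
        assert trace.occupancy[-1, 1] > 0.5  # most survivors progressed
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)


class TestDecisionTree:
    def test_chance_probabilities_sum_to_one_everywhere(self, baseline_inputs):
        tree = build_decision_tree(
            baseline_inputs.params, baseline_inputs.payoffs, baseline_inputs.utilities
        )
        tree.validate()  # raises on any violation

    def test_sf_root_split_matches_resection_probability(self, baseline_inputs):
        sf = build_strategy_tree(
            "SF", baseline_inputs.params, baseline_inputs.payoffs, baseline_inputs.utilities
        )
        probs = sorted(p for p, _ in sf.children)
        assert probs == pytest.approx([0.06, 0.94])

    def test_nat_residual_no_surgery_mass(self, baseline_inputs):
        nat = build_strategy_tree(
            "NAT", baseline_inputs.params, baseline_inputs.payoffs, baseline_inputs.utilities
        )
        leaves = {leaf.cohort: p for p, leaf in nat.leaves()}
        assert leaves["nat_no_surgery"] == pytest.approx(1 - 0.41 - 0.10)

    def test_baseline_intention_to_treat_rollup(self, baseline_inputs):
        tree = build_decision_tree(
            baseline_inputs.params, baseline_inputs.payoffs, baseline_inputs.utilities
        )
        out = expected_value_rollup(tree)
        assert out.sf.life_months == pytest.approx(23.72, rel=0.02)
        assert out.sf.qalms == pytest.approx(18.51, rel=0.02)
        assert out.nat.life_months == pytest.approx(20.22, rel=0.02)
        assert out.nat.qalms == pytest.approx(16.26, rel=0.02)

    def test_itt_equals_probability_weighted_leaf_sum(self, baseline_inputs):
        tree = build_decision_tree(
            baseline_inputs.params, baseline_inputs.payoffs, baseline_inputs.utilities
        )
        out = expected_value_rollup(tree)
        table = cohort_table(tree)
        sf = table[table.strategy == "SF"]
        assert (sf.probability * sf.life_months).sum() == pytest.approx(
            out.sf.life_months, abs=1e-9
        )
        assert (sf.probability * sf.qalms).sum() == pytest.approx(out.sf.qalms, abs=1e-9)

    def test_rollup_linear_in_payoffs(self, baseline_inputs):
        from dataclasses import replace

        scaled = {
            label: replace(
                p,
                life_months=2.0 * p.life_months,
                qalms=2.0 * p.qalms,
                variants={k: 2.0 * v for k, v in p.variants.items()},
            )
            for label, p in baseline_inputs.payoffs.items()
        }
        base = expected_value_rollup(
            build_decision_tree(
                baseline_inputs.params, baseline_inputs.payoffs, baseline_inputs.utilities
            )
        )
        doubled = expected_value_rollup(
            build_decision_tree(baseline_inputs.params, scaled, baseline_inputs.utilities)
        )
        assert doubled.sf.qalms == pytest.approx(2.0 * base.sf.qalms, abs=1e-9)
        assert doubled.nat.life_months == pytest.approx(2.0 * base.nat.life_months, abs=1e-9)

    def test_degenerate_probabilities_single_effective_path(self, baseline_inputs):
        params = baseline_inputs.params
        for pid, v in [
            ("sf.resect", 1.0),
            ("sf.poc5", 0.0),
            ("sf.r0", 1.0),
            ("sf.adjuvant", 1.0),
            ("sf.poc34", 0.0),
            ("sf.adj_tox3", 0.0),
        ]:
            params = params.with_value(pid, v)
        sf = build_strategy_tree(
            "SF", params, baseline_inputs.payoffs, baseline_inputs.utilities
        )
        live = [(p, leaf) for p, leaf in sf.leaves() if p > 0]
        assert len(live) == 1
        assert live[0][1].cohort == "sf_r0_adjuvant"
        assert live[0][1].payoff_lm == pytest.approx(30.96)

    def test_fatal_complication_accrues_zero(self, baseline_inputs):
        tree = build_decision_tree(
            baseline_inputs.params, baseline_inputs.payoffs, baseline_inputs.utilities
        )
        table = cohort_table(tree)
        death = table[table.cohort.str.contains("operative_death")]
        assert (death.life_months == 0).all()
        assert (death.qalms == 0).all()

    def test_cohort_table_contains_printed_nat_r0_row(self, baseline_inputs):
        tree = build_decision_tree(
            baseline_inputs.params, baseline_inputs.payoffs, baseline_inputs.utilities
        )
        table = cohort_table(tree)
        nat_r0 = table[table.cohort == "nat_r0"]
        assert set(nat_r0.life_months) == {35.05}

    def test_trace_mode_life_months_match_direct_mode(self, baseline_inputs):
        direct = build_decision_tree(
            baseline_inputs.params, baseline_inputs.payoffs, baseline_inputs.utilities, "direct"
        )
        trace = build_decision_tree(
            baseline_inputs.params, baseline_inputs.payoffs, baseline_inputs.utilities, "trace"
        )
        out_d = expected_value_rollup(direct)
        out_t = expected_value_rollup(trace)
        assert out_t.sf.life_months == pytest.approx(out_d.sf.life_months, abs=1e-4)
        assert out_t.nat.life_months == pytest.approx(out_d.nat.life_months, abs=1e-4)

    def test_trace_mode_qalms_bounded_by_life_months(self, baseline_inputs):
        tree = build_decision_tree(
            baseline_inputs.params, baseline_inputs.payoffs, baseline_inputs.utilities, "trace"
        )
        table = cohort_table(tree)
        assert (table.qalms <= table.life_months + 1e-9).all()

    def test_rollup_monotone_in_leaf_payoff(self, baseline_inputs):
        from dataclasses import replace

        bumped = dict(baseline_inputs.payoffs)
        bumped["nat_r0"] = replace(bumped["nat_r0"], life_months=40.0)
        base = expected_value_rollup(
            build_decision_tree(
                baseline_inputs.params, baseline_inputs.payoffs, baseline_inputs.utilities
            )
        )
        up = expected_value_rollup(
            build_decision_tree(baseline_inputs.params, bumped, baseline_inputs.utilities)
        )
        assert up.nat.life_months > base.nat.life_months
        assert up.sf.life_months == pytest.approx(base.sf.life_months)


class TestModelResults:
    def test_fit_returns_summary_with_both_strategies(self, baseline_results):
        text = baseline_results.summary()
        assert "SF" in text and "NAT" in text
        assert f"{baseline_results.sf.life_months:8.2f}".strip() in text

    def test_incremental_difference_sign(self, baseline_results):
        # at baseline the surgery-first strategy is ahead on both scales
        assert baseline_results.incremental_lm > 0
        assert baseline_results.incremental_qalm > 0

    def test_collapsed_cohort_table_baseline_qalms(self, baseline_results):
        tab = baseline_results.cohort_table()
        row = tab[(tab.strategy == "SF") & (tab.cohort == "sf_r0_adjuvant")].iloc[0]
        assert row.qalms == pytest.approx(24.86)
        assert row.qalms_mixed < row.qalms  # variant mixing can only lower it

    def test_from_study_records_repools_parameter(self, baseline_model):
        from pdacpath.simulate import SyntheticPoolConfig, generate_study_pool
        from pdacpath.model import PathwayDecisionModel

        cfg = SyntheticPoolConfig(
            k_studies=40, n_range=(80, 120), true_proportions={"resect": 0.55}, tau=0.02
        )
        pool = generate_study_pool(cfg, seed=7)
        model = PathwayDecisionModel.from_study_records(
            pool, {"nat.resect": "resect"}, base=baseline_model
        )
        assert model.params.get("nat.resect").point == pytest.approx(0.55, abs=0.05)
        assert model.params.get("sf.resect").point == 0.94  # untouched
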