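"""Markov engine: transition structure, discounting, accrual, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from icbt_cea import (HealthState, ModelConfig, Strategy, build_transition_model,
                      discount_factor, initial_distribution, run_cohort,
                      run_strategy, sample_parameter_set)
from icbt_cea.tree import InitialDistribution


class TestTransitionModel:
    def test_relapse_splits_by_severity_mix(self, params):
        tm = build_transition_model(params)
        assert tm.probability(HealthState.WELL, HealthState.MILD) == \
            pytest.approx(0.0244 * 0.243)
        assert tm.probability(HealthState.WELL, HealthState.MODERATE) == \
            pytest.approx(0.0244 * 0.757 * 0.5)

    def test_depressed_mortality_carries_relative_risk(self, params):
        tm = build_transition_model(params)
        assert tm.probability(HealthState.MILD, HealthState.DEAD) == \
            pytest.approx(2.5e-5 * 1.81)
        assert tm.probability(HealthState.WELL, HealthState.DEAD) == \
            pytest.approx(2.5e-5)

    def test_well_absorbing_without_relapse_or_death(self, params):
        p = params.with_overrides({"relapse_monthly": 0.0,
                                   "mortality_monthly": 0.0}, strict=False)
        tm = build_transition_model(p)
        assert tm.probability(HealthState.WELL, HealthState.WELL) == 1.0

    def test_tree_mode_has_no_lateral_severity_moves(self, params):
        tm = build_transition_model(params, ModelConfig(severity_mix="tree"))
        assert tm.probability(HealthState.MILD, HealthState.MODERATE) == 0.0
        assert tm.probability(HealthState.MILD, HealthState.MILD) == \
            pytest.approx(1.0 - 0.0054 - 2.5e-5 * 1.81)

    def test_stationary_symptomatic_share(self, params):
        # with mortality off, the well<->symptomatic chain has the closed-form
        # stationary split relapse/(relapse + remission)
        p = params.with_overrides({"mortality_monthly": 0.0}, strict=False)
        m = build_transition_model(p).matrix
        w, eigv = np.linalg.eig(m.T)
        stat = np.real(eigv[:, np.argmax(np.real(w))])
        stat = np.abs(stat) / np.abs(stat).sum()
        assert stat[1:4].sum() == pytest.approx(0.0244 / (0.0244 + 0.0054))
        assert stat[1:4].sum() == pytest.approx(0.818792, abs=5e-7)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_rows_stochastic_for_random_parameters(self, params, seed):
        for mode in ("relapse_proportions", "tree"):
            m = build_transition_model(sample_parameter_set(params, seed),
                                       ModelConfig(severity_mix=mode)).matrix
            assert m.sum(axis=1) == pytest.approx(np.ones(5), abs=1e-12)
            assert m.min() >= 0.0


class TestDiscounting:
    def test_closed_form_factors(self):
        assert discount_factor(0, 0.03) == 1.0
        assert discount_factor(12, 0.03) == pytest.approx(1 / 1.03)
        assert discount_factor(60, 0.0) == 1.0

    def test_rate_below_minus_one_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -1.5)

    def test_discounting_only_shrinks_totals(self, params):
        undiscounted = params.with_overrides({"discount_annual": 0.0}, strict=False)
        for strategy in Strategy:
            d = run_strategy(strategy, params)
            u = run_strategy(strategy, undiscounted)
            assert d.total_cost < u.total_cost
            assert d.total_qaly < u.total_qaly


class TestCohort:
    def test_all_well_cohort_is_a_fixed_point(self, params):
        p = params.with_overrides({"relapse_monthly": 0.0,
                                   "mortality_monthly": 0.0,
                                   "dropout_monthly_well": 0.0}, strict=False)
        init = InitialDistribution(1.0, 0.0, 0.0, 0.0, 0.0)
        trace = run_cohort(init, build_transition_model(p), p)
        assert trace.occupancy == pytest.approx(
            np.tile([1, 0, 0, 0, 0], (61, 1)), abs=1e-12)

    def test_symptomatic_dropout_matches_survival_product(self, params):
        p = params.with_overrides({"mortality_monthly": 0.0,
                                   "remission_monthly": 0.0}, strict=False)
        init = InitialDistribution(0.0, 1.0, 0.0, 0.0, 0.0)
        trace = run_cohort(init, build_transition_model(p), p)
        assert trace.cum_dropout[-1] == pytest.approx(1 - (1 - 0.00193) ** 60)

    def test_occupancy_conserved_and_dropout_monotone(self, params, perturbed_sets):
        for ps in perturbed_sets[:10]:
            init = initial_distribution(Strategy.INTERNET, ps)
            trace = run_cohort(init, build_transition_model(ps), ps)
            assert trace.occupancy.sum(axis=1) == pytest.approx(
                np.ones(61), abs=1e-9)
            assert np.all(np.diff(trace.cum_dropout) >= -1e-15)
            assert trace.cum_dropout[-1] <= 1.0
            assert np.all(trace.disc_cost >= 0) and np.all(trace.disc_qaly >= 0)

    def test_qaly_bounded_by_perfect_health_horizon(self, params, perturbed_sets):
        for ps in perturbed_sets[:10]:
            out = run_strategy(Strategy.INTERNET, ps)
            assert out.total_qaly <= 5 * 0.92


class TestAccrual:
    def test_hospitalization_component_for_severe_cohort(self, params):
        # an all-severe cohort accrues 0.0178 x 1500 $ of inpatient cost per
        # month on top of outpatient care; probe it via a one-cycle horizon
        p = params.with_overrides({"horizon_months": 1, "discount_annual": 0.0,
                                   "dropout_monthly_dep": 0.0,
                                   "remission_monthly": 0.0,
                                   "mortality_monthly": 0.0,
                                   "prop_mild_relapse": 0.0,
                                   "prop_moderate_among_modsev": 0.0},
                                  strict=False)
        init = InitialDistribution(0.0, 0.0, 0.0, 1.0, 0.0)
        trace = run_cohort(init, build_transition_model(p), p)
        assert trace.disc_cost[0] == pytest.approx(231 + 0.0178 * 1500)
        assert trace.disc_qaly[0] == pytest.approx(0.33 / 12)

    def test_well_cohort_monthly_qaly(self, params):
        p = params.with_overrides({"horizon_months": 1, "discount_annual": 0.0,
                                   "relapse_monthly": 0.0,
                                   "mortality_monthly": 0.0,
                                   "dropout_monthly_well": 0.0}, strict=False)
        init = InitialDistribution(1.0, 0.0, 0.0, 0.0, 0.0)
        trace = run_cohort(init, build_transition_model(p), p)
        assert trace.disc_qaly[0] == pytest.approx(0.80 / 12)
        assert trace.disc_cost[0] == 0.0

    def test_dead_cohort_accrues_nothing(self, params):
        # certain immediate death: every end-of-cycle state is dead, so no
        # cost or QALY ever accrues
        p = params.with_overrides({"mortality_monthly": 1.0,
                                   "relapse_monthly": 0.0,
                                   "remission_monthly": 0.0,
                                   "rr_mortality_depressed": 1.0,
                                   "horizon_months": 3}, strict=False)
        init = InitialDistribution(1.0, 0.0, 0.0, 0.0, 0.0)
        trace = run_cohort(init, build_transition_model(p), p)
        assert np.all(trace.occupancy[1:, HealthState.DEAD] == 1.0)
        assert trace.disc_cost.sum() == 0.0
        assert trace.disc_qaly.sum() == 0.0


class TestStrategyOutcome:
    def test_zero_horizon_leaves_program_cost_only(self, params):
        p = params.with_overrides({"horizon_months": 0}, strict=False)
        out = run_strategy(Strategy.INTERNET, p)
        assert out.total_cost == pytest.approx(0.753 * 41.4447)
        assert out.total_qaly == 0.0

    def test_runs_are_bit_identical(self, params):
        a = run_strategy(Strategy.INTERNET, params)
        b = run_strategy(Strategy.INTERNET, params)
        assert (a.total_cost, a.total_qaly, a.dropout_prob) == \
            (b.total_cost, b.total_qaly, b.dropout_prob)

    def test_equal_arm_parameters_give_identical_outcomes(self, params):
        p = params.with_overrides(
            {"accept_internet": params.accept_inperson,
             "comply_internet": params.comply_inperson,
             "therapist_time_share_internet": 1.0,
             "platform_overhead": 0.0}, strict=False)
        a = run_strategy(Strategy.INTERNET, p)
        b = run_strategy(Strategy.IN_PERSON, p)
        assert a.total_cost == pytest.approx(b.total_cost)
        assert a.total_qaly == pytest.approx(b.total_qaly)
        assert a.dropout_prob == pytest.approx(b.dropout_prob)
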