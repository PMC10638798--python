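"""Cohort propagation, discounting, accrual conventions and engine oracles."""

import numpy as np
import pytest

from bcscea import (
    HealthState,
    LifeTable,
    RecurrenceSchedule,
    Strategy,
    build_matrix,
    default_parameters,
    expected_time_in_state,
    run_cohort,
)


def single_state_params(**overrides):
    """Base case stripped to a cohort that stays cancer-free forever."""
    params = default_parameters()
    params.transitions.tpA2D = 0.0
    flat = RecurrenceSchedule(((0, 30, 0.0),))
    for strategy in Strategy:
        params.transitions.recurrence_schedules[strategy] = flat
    for key, value in overrides.items():
        setattr(params, key, value)
    return params


class TestDegenerateCohorts:
    def test_single_cycle_undiscounted_qaly_is_state_a_utility(
        self, zero_mortality
    ):
        params = single_state_params(horizon_cycles=1)
        params.discount.outcome_rate = 0.0
        result = run_cohort(Strategy.LUMPECTOMY_NO_RT, params, zero_mortality)
        assert result.qaly == pytest.approx(0.87)

    def test_single_cycle_discounted_qaly(self, zero_mortality):
        params = single_state_params(horizon_cycles=1)
        result = run_cohort(Strategy.LUMPECTOMY_NO_RT, params, zero_mortality)
        assert result.qaly == pytest.approx(0.87 / 1.03)

    def test_time_in_state_single_cycle(self, zero_mortality):
        params = single_state_params(horizon_cycles=1)
        result = run_cohort(Strategy.MASTECTOMY, params, zero_mortality)
        assert expected_time_in_state(
            result.trace, HealthState.CANCER_FREE
        ) == pytest.approx(1.0)

    def test_immediate_death_leaves_no_time_in_a(self):
        ages = np.arange(0, 121)
        certain_death = LifeTable(ages=ages, q=np.ones_like(ages, dtype=float))
        params = single_state_params()
        result = run_cohort(Strategy.MASTECTOMY, params, certain_death)
        assert expected_time_in_state(
            result.trace, HealthState.CANCER_FREE
        ) == pytest.approx(0.0)
        assert result.qaly == pytest.approx(0.0)


class TestConservationAndTrace:
    def test_occupancy_rows_sum_to_one(self, base_results):
        for result in base_results.values():
            sums = result.trace.occupancy.sum(axis=1)
            assert np.allclose(sums, 1.0, atol=1e-10)
            assert np.all((result.trace.occupancy >= 0)
                          & (result.trace.occupancy <= 1))

    def test_death_occupancy_non_decreasing(self, base_results):
        f = HealthState.DEATH.index
        for result in base_results.values():
            assert np.all(np.diff(result.trace.occupancy[:, f]) >= -1e-15)

    def test_trace_frame_layout(self, base_results):
        frame = base_results[Strategy.MASTECTOMY].trace.to_frame()
        assert len(frame) == 30
        assert frame["age"].iloc[0] == 58
        assert {"occupancy_A", "occupancy_F", "cycle_cost_discounted",
                "cycle_qaly"} <= set(frame.columns)

    def test_totals_recoverable_from_trace(self, base_results):
        result = base_results[Strategy.LUMPECTOMY_RT]
        frame = result.trace.to_frame()
        entry = 50_352.0
        assert entry + frame["cycle_cost_discounted"].sum() == pytest.approx(
            result.cost_healthcare
        )
        assert frame["cycle_qaly_discounted"].sum() == pytest.approx(result.qaly)


class TestDiscountMonotonicity:
    @pytest.mark.parametrize("attr", ["cost_rate", "outcome_rate"])
    def test_totals_non_increasing_in_rate(self, lifetable, attr):
        previous = None
        for rate in (0.0, 0.03, 0.06):
            params = default_parameters()
            setattr(params.discount, attr, rate)
            result = run_cohort(Strategy.LUMPECTOMY_RT, params, lifetable)
            value = result.qaly if attr == "outcome_rate" else (
                result.cost_healthcare
            )
            if previous is not None:
                assert value < previous
            previous = value


class TestZeroLimits:
    def test_zero_utilities_give_zero_qalys(self, lifetable, params):
        for strategy in Strategy:
            params.utilities.state_a[strategy] = 0.0
        for name in ("ub", "uc", "ud", "ue"):
            setattr(params.utilities, name, 0.0)
        result = run_cohort(Strategy.MASTECTOMY, params, lifetable)
        assert result.qaly == 0.0

    def test_zero_costs_give_zero_totals(self, lifetable, params):
        for strategy in Strategy:
            params.costs.baseline_cost[strategy] = 0.0
            params.costs.stateB_cost[strategy] = 0.0
            params.costs.informal_care[strategy] = 0.0
        params.costs.stateD_cost = 0.0
        params.costs.productivity_gain = 0.0
        result = run_cohort(Strategy.LUMPECTOMY_RT, params, lifetable)
        assert result.cost_healthcare == 0.0
        assert result.cost_societal == 0.0


class TestMatrixPowerOracle:
    def test_time_homogeneous_trace_equals_matrix_power(self, params):
        """Frozen recurrence + flat mortality: trace row t must equal v0 M^t."""
        flat_rate = RecurrenceSchedule(((0, 30, 34.0),))
        for strategy in Strategy:
            params.transitions.recurrence_schedules[strategy] = flat_rate
        ages = np.arange(0, 121)
        table = LifeTable(ages=ages, q=np.full(ages.shape, 0.01))
        result = run_cohort(Strategy.LUMPECTOMY_NO_RT, params, table)
        matrix = build_matrix(
            Strategy.LUMPECTOMY_NO_RT, 0, 58, params, table
        ).matrix
        v0 = np.zeros(6)
        v0[0] = 1.0
        for t in range(31):
            expected = v0 @ np.linalg.matrix_power(matrix, t)
            assert np.allclose(result.trace.occupancy[t], expected, atol=1e-10)


class TestStrategyOrdering:
    def test_qaly_ordering_matches_published_pattern(self, base_results):
        """Lumpectomy+RT accrues the most QALYs; mastectomy trails it.

        Mastectomy vs lumpectomy-without-RT is a knife edge: the lower
        recurrence of mastectomy nearly offsets its lower cancer-free
        utility, so that ordering flips with the weight of background
        mortality (under heavier, real-world-like schedules mastectomy is
        strictly last).  Only the robust ordering is asserted here; the
        mastectomy-last pattern is asserted on the PSA means, where sampled
        entry ages supply that heavier mortality mix.
        """
        qalys = {s: r.qaly for s, r in base_results.items()}
        assert qalys[Strategy.LUMPECTOMY_RT] > qalys[Strategy.LUMPECTOMY_NO_RT]
        assert qalys[Strategy.LUMPECTOMY_RT] > qalys[Strategy.MASTECTOMY]
        assert qalys[Strategy.MASTECTOMY] == pytest.approx(
            qalys[Strategy.LUMPECTOMY_NO_RT], rel=0.01
        )

    def test_irradiation_extends_time_cancer_free(self, base_results):
        time_a = {
            s: expected_time_in_state(r.trace, HealthState.CANCER_FREE)
            for s, r in base_results.items()
        }
        assert time_a[Strategy.LUMPECTOMY_RT] > time_a[Strategy.LUMPECTOMY_NO_RT]


class TestSocietalConventions:
    def test_flat_annuity_gap_matches_closed_form(self, base_results, params):
        """Societal minus healthcare = informal-care annuity - productivity."""
        annuity30 = sum(1.03 ** -(t + 1) for t in range(30))
        annuity10 = sum(1.03 ** -(t + 1) for t in range(10))
        result = base_results[Strategy.MASTECTOMY]
        assert result.cost_societal - result.cost_healthcare == pytest.approx(
            10_003.0 * annuity30
        )
        result = base_results[Strategy.LUMPECTOMY_RT]
        assert result.cost_societal - result.cost_healthcare == pytest.approx(
            10_003.0 * annuity30 - 4_104.0 * annuity10
        )
        result = base_results[Strategy.LUMPECTOMY_NO_RT]
        assert result.cost_societal - result.cost_healthcare == pytest.approx(
            5_002.0 * annuity30 - 4_104.0 * annuity10
        )

    def test_informal_care_scope_ordering(self, lifetable):
        """state_D accrues least informal care, flat annuity the most."""
        gaps = {}
        for scope in ("state_D", "all_alive", "flat_annuity"):
            params = default_parameters()
            params.informal_care_scope = scope
            result = run_cohort(Strategy.MASTECTOMY, params, lifetable)
            gaps[scope] = result.cost_societal - result.cost_healthcare
        assert gaps["state_D"] < gaps["all_alive"] < gaps["flat_annuity"]

    def test_entry_cost_switch(self, lifetable, base_results):
        params = default_parameters()
        params.charge_entry_cost = False
        result = run_cohort(Strategy.MASTECTOMY, params, lifetable)
        assert result.cost_healthcare == pytest.approx(
            base_results[Strategy.MASTECTOMY].cost_healthcare - 87_670.0
        )
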