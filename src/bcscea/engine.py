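"""Deterministic cohort simulation: occupancy trace, discounted costs, QALYs.

The cohort enters fully cancer-free and is propagated for ``horizon_cycles``
one-year cycles by left-multiplication with the per-cycle transition matrix.
Cycle ``t`` (0-based) is valued on the end-of-cycle occupancy (trace row
``t + 1``) and discounted by ``1/(1+rate)**(t+1)``.

Cost accrual (healthcare perspective)
-------------------------------------
* the arm baseline (surgery + hospitalisation) cost is charged once on
  entry, undiscounted, and — matching the published totals — again for every
  cycle spent cancer-free as a running State A cost;
* the recurrence state accrues the arm's State B treatment cost per cycle of
  occupancy, the metastasis state the common State D cost; remission states
  and death are costless.

Societal add-ons
----------------
Informal care accrues by default as a flat discounted annuity over the whole
horizon (the convention recovered from the published perspective gaps), with
per-cycle-in-metastasis and per-cycle-alive variants available; the
productivity gain of the lumpectomy arms is a flat (optionally
survival-weighted) 10-year discounted annuity subtracted from costs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .parameters import ModelParameters
from .states import N_STATES, HealthState, Strategy
from .synthetic_data import LifeTable
from .transitions import build_matrix

logger = logging.getLogger(__name__)

__all__ = ["CohortTrace", "StrategyResult", "run_cohort",
           "expected_time_in_state"]


@dataclass
class CohortTrace:
    """State-occupancy history plus per-cycle (un)discounted accruals.

    ``occupancy`` has ``horizon + 1`` rows (row 0 is the initial
    distribution, all mass cancer-free) and one column per state A..F.
    The per-cycle vectors are indexed by cycle ``t = 0..horizon-1`` and refer
    to end-of-cycle valuation; ``cycle_cost``/``cycle_cost_societal`` exclude
    the one-off entry cost, which is reported on the result object.
    """

    occupancy: np.ndarray
    cycle_cost: np.ndarray
    cycle_cost_societal: np.ndarray
    cycle_qaly: np.ndarray
    strategy: Strategy
    entry_age: int
    cost_discount: np.ndarray
    outcome_discount: np.ndarray
    #: cycles whose transition row needed clipping (death capped at 1).
    clipped_cycles: int = 0

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cycle export (cycle, age, occupancy, accruals)."""
        t = np.arange(self.horizon)
        frame = pd.DataFrame({"cycle": t, "age": self.entry_age + t})
        for j, state in enumerate(HealthState):
            frame[f"occupancy_{state.value}"] = self.occupancy[1:, j]
        frame["cycle_cost"] = self.cycle_cost
        frame["cycle_cost_societal"] = self.cycle_cost_societal
        frame["cycle_qaly"] = self.cycle_qaly
        frame["cycle_cost_discounted"] = self.cycle_cost * self.cost_discount
        frame["cycle_cost_societal_discounted"] = (
            self.cycle_cost_societal * self.cost_discount
        )
        frame["cycle_qaly_discounted"] = self.cycle_qaly * self.outcome_discount
        return frame


@dataclass
class StrategyResult:
    """Discounted totals for one strategy (both cost perspectives)."""

    strategy: Strategy
    qaly: float
    cost_healthcare: float
    cost_societal: float
    trace: CohortTrace

    def cost(self, perspective: str) -> float:
        if perspective == "healthcare":
            return self.cost_healthcare
        if perspective == "societal":
            return self.cost_societal
        raise ValidationError(f"unknown perspective {perspective!r}")


def run_cohort(
    strategy: Strategy,
    params: ModelParameters,
    lifetable: LifeTable,
) -> StrategyResult:
    """Run the deterministic cohort model for one strategy.

    The life table must cover the cohort's ages over the horizon (lookups
    clamp only for PSA-sampled extreme entry ages).
    """
    params.validate()
    horizon = params.horizon_cycles
    occupancy = np.zeros((horizon + 1, N_STATES))
    occupancy[0, HealthState.CANCER_FREE.index] = 1.0

    utilities = np.array(params.utilities.weights_for(strategy))
    state_costs = np.zeros(N_STATES)
    if params.state_a_running_cost:
        state_costs[HealthState.CANCER_FREE.index] = (
            params.costs.baseline_cost[strategy]
        )
    state_costs[HealthState.LOCOREGIONAL_RECURRENCE.index] = (
        params.costs.stateB_cost[strategy]
    )
    state_costs[HealthState.METASTASIS.index] = params.costs.stateD_cost

    cdr, odr = params.discount.cost_rate, params.discount.outcome_rate
    t = np.arange(horizon)
    cost_discount = (1.0 + cdr) ** -(t + 1)
    outcome_discount = (1.0 + odr) ** -(t + 1)

    cycle_cost = np.zeros(horizon)
    cycle_cost_soc = np.zeros(horizon)
    cycle_qaly = np.zeros(horizon)
    clipped_cycles = 0

    informal = params.costs.informal_care[strategy]
    productivity = (
        params.costs.productivity_gain if strategy.is_lumpectomy else 0.0
    )
    prod_years = min(params.costs.productivity_years, horizon)

    for cycle in range(horizon):
        age = params.entry_age + cycle
        tm = build_matrix(strategy, cycle, age, params, lifetable)
        clipped_cycles += tm.clipped
        end = occupancy[cycle] @ tm.matrix
        occupancy[cycle + 1] = end
        if params.half_cycle_correction:
            valued = 0.5 * (occupancy[cycle] + end)
        else:
            valued = end
        alive = 1.0 - valued[HealthState.DEATH.index]
        cycle_qaly[cycle] = valued @ utilities
        hc = valued @ state_costs
        cycle_cost[cycle] = hc

        soc = hc
        if params.informal_care_scope == "flat_annuity":
            soc += informal
        elif params.informal_care_scope == "all_alive":
            soc += informal * alive
        else:  # state_D
            soc += informal * valued[HealthState.METASTASIS.index]
        if cycle < prod_years:
            weight = alive if params.productivity_alive_weighted else 1.0
            soc -= productivity * weight
        cycle_cost_soc[cycle] = soc

    if clipped_cycles:
        logger.debug(
            "%s: exit probabilities clipped in %d of %d cycles (extreme "
            "entry age or sampled inputs); death capped at 1 there",
            strategy.value, clipped_cycles, horizon,
        )
    entry_cost = (
        params.costs.baseline_cost[strategy] if params.charge_entry_cost else 0.0
    )
    trace = CohortTrace(
        occupancy=occupancy,
        cycle_cost=cycle_cost,
        cycle_cost_societal=cycle_cost_soc,
        cycle_qaly=cycle_qaly,
        strategy=strategy,
        entry_age=params.entry_age,
        cost_discount=cost_discount,
        outcome_discount=outcome_discount,
        clipped_cycles=clipped_cycles,
    )
    return StrategyResult(
        strategy=strategy,
        qaly=float(cycle_qaly @ outcome_discount),
        cost_healthcare=float(entry_cost + cycle_cost @ cost_discount),
        cost_societal=float(entry_cost + cycle_cost_soc @ cost_discount),
        trace=trace,
    )


def run_all(params: ModelParameters, lifetable: LifeTable
            ) -> dict[Strategy, StrategyResult]:
    """Run all three strategies on common inputs."""
    return {s: run_cohort(s, params, lifetable) for s in Strategy}


def expected_time_in_state(trace: CohortTrace, state: HealthState) -> float:
    """Undiscounted person-years spent in ``state`` over the horizon.

    Sums end-of-cycle occupancy across cycles 1..horizon.
    """
    return float(trace.occupancy[1:, state.index].sum())
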