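"""Rate/probability conversions and per-cycle transition matrices.

Published evidence arrives in two forms and both are converted to annual
probabilities through the exponential (constant-hazard) model
``p = 1 - exp(-r t)``:

* incidence rates per 1000 person-years (the time-dependent cancer-free ->
  recurrence input), with t = one cycle = one year;
* cumulative incidences over a stated follow-up, first inverted to a rate
  ``r = -ln(1 - CI) / T``.

:func:`build_matrix` assembles the 6x6 row-stochastic matrix for one
(strategy, cycle, age), overlaying age-specific background mortality on
every living state: it *is* the death exit of the cancer-free and remission
states and is *added* to the disease-specific death exits of the recurrence
and metastasis states, with the stay-probability absorbing the complement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import InfeasibleParametersError, ParameterError
from .parameters import ModelParameters, RecurrenceSchedule
from .states import ALLOWED_TRANSITIONS, N_STATES, HealthState, Strategy
from .synthetic_data import LifeTable

logger = logging.getLogger(__name__)

_A, _B, _C, _D, _E, _F = range(N_STATES)

#: boolean mask of entries that may be non-zero (arcs + self-loops).
STRUCTURE_MASK = np.zeros((N_STATES, N_STATES), dtype=bool)
for _i in range(N_STATES):
    STRUCTURE_MASK[_i, _i] = True
for _frm, _to in ALLOWED_TRANSITIONS:
    STRUCTURE_MASK["ABCDEF".index(_frm), "ABCDEF".index(_to)] = True


def prob_from_rate(rate_per_1000py: float, t: float = 1.0) -> float:
    """Annual probability from an incidence rate per 1000 person-years.

    ``p = 1 - exp(-(rate/1000) * t)`` with t defaulting to the one-year
    cycle length.
    """
    if rate_per_1000py < 0:
        raise ParameterError(f"incidence rate must be >= 0, got {rate_per_1000py}")
    return 1.0 - math.exp(-rate_per_1000py / 1000.0 * t)


def prob_from_cumulative_incidence(ci: float, follow_up_years: float) -> float:
    """Annual probability from a cumulative incidence over ``follow_up_years``.

    Inverts the exponential model: ``r = -ln(1 - CI) / T`` then
    ``p = 1 - exp(-r)``.  Monotone increasing in CI, decreasing in T.
    """
    if not 0.0 <= ci < 1.0:
        raise ParameterError(
            f"cumulative incidence must be in [0, 1), got {ci}"
        )
    if follow_up_years <= 0:
        raise ParameterError(
            f"follow-up must be positive, got {follow_up_years}"
        )
    rate = -math.log(1.0 - ci) / follow_up_years
    return 1.0 - math.exp(-rate)


def mastectomy_schedule_from_irr(
    lump_no_rt_schedule: RecurrenceSchedule, irr: float = 1.27
) -> RecurrenceSchedule:
    """Transfer a mastectomy recurrence schedule from the lumpectomy one.

    No Swedish trial reports mastectomy recurrence for in situ disease, so
    the mastectomy incidences are obtained by dividing the Swedish
    lumpectomy-without-irradiation incidences by the incidence-rate ratio
    observed between the two procedures in a US trial (1.27).
    """
    if irr <= 0:
        raise ParameterError(f"incidence rate ratio must be positive, got {irr}")
    return lump_no_rt_schedule.scaled(1.0 / irr)


def tpA2B_at(
    strategy: Strategy,
    cycle: int,
    schedules: dict[Strategy, RecurrenceSchedule],
) -> float:
    """Time-dependent cancer-free -> recurrence probability for one cycle.

    Cycle t (0-based) falls in the follow-up window containing t: with the
    packaged [0,5)/[5,10)/[10,30) windows, cycles 0-4 use the first period,
    5-9 the second, 10-29 the third.
    """
    schedule = schedules[strategy]
    if not schedule.start <= cycle < schedule.end:
        raise ParameterError(
            f"cycle {cycle} outside schedule coverage "
            f"[{schedule.start}, {schedule.end})"
        )
    return prob_from_rate(schedule.rate_at(cycle))


@dataclass(frozen=True)
class TransitionMatrix:
    """A validated 6x6 one-cycle transition matrix with its context."""

    matrix: np.ndarray
    strategy: Strategy
    cycle: int
    age: int
    clipped: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (N_STATES, N_STATES):
            raise InfeasibleParametersError(f"matrix shape {m.shape} != 6x6")
        if np.any((m < 0) | (m > 1)):
            row = int(np.argmax(np.any((m < 0) | (m > 1), axis=1)))
            raise InfeasibleParametersError(
                f"transition probability outside [0, 1] in row "
                f"{'ABCDEF'[row]} (strategy={self.strategy.value}, "
                f"cycle={self.cycle}, age={self.age})"
            )
        rowsums = m.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-12):
            row = int(np.argmax(np.abs(rowsums - 1.0)))
            raise InfeasibleParametersError(
                f"row {'ABCDEF'[row]} sums to {rowsums[row]!r}, not 1"
            )
        if np.any(m[~STRUCTURE_MASK] != 0.0):
            raise InfeasibleParametersError(
                "non-zero entry outside the model's transition graph"
            )


def _row(stay_index: int, exits: dict[int, float], strategy: Strategy,
         cycle: int, age: int) -> tuple[np.ndarray, bool]:
    """Assemble one row: named exits, stay-probability as complement.

    If the exits alone exceed 1 (possible only under extreme sampled or
    user-supplied inputs, never with the base case), death is capped at 1,
    other exits are scaled to 0, and a warning is logged.
    """
    row = np.zeros(N_STATES)
    total_exit = sum(exits.values())
    clipped = False
    if total_exit > 1.0:
        logger.debug(
            "row %s exits sum to %.4f > 1 at strategy=%s cycle=%d age=%d; "
            "capping death at 1",
            "ABCDEF"[stay_index], total_exit, strategy.value, cycle, age,
        )
        row[_F] = 1.0
        clipped = True
    else:
        for idx, p in exits.items():
            row[idx] = p
        row[stay_index] = 1.0 - total_exit
    return row, clipped


def build_matrix(
    strategy: Strategy,
    cycle: int,
    age: int,
    params: ModelParameters,
    lifetable: LifeTable,
) -> TransitionMatrix:
    """One-cycle transition matrix for ``strategy`` at ``cycle`` and ``age``.

    ``age`` is the cohort age at the start of the cycle; the background
    mortality ``mor_gp`` is looked up at that integer age (no
    interpolation).  With ``params.background_mortality_additive`` (the
    default) the recurrence/metastasis death exits are disease-specific
    probabilities plus ``mor_gp``; switched off, they are treated as already
    all-cause.
    """
    tr = params.transitions
    mor_gp = lifetable.q_at(age)
    tpA2B = tpA2B_at(strategy, cycle, tr.recurrence_schedules)
    overlay = mor_gp if params.background_mortality_additive else 0.0

    rows = {}
    any_clipped = False
    rows[_A], c = _row(_A, {_B: tpA2B, _D: tr.tpA2D, _F: mor_gp},
                       strategy, cycle, age)
    any_clipped |= c
    rows[_B], c = _row(_B, {_C: tr.tpB2C, _F: tr.tpB2F + overlay},
                       strategy, cycle, age)
    any_clipped |= c
    rows[_C], c = _row(_C, {_D: tr.tpC2D, _F: mor_gp}, strategy, cycle, age)
    any_clipped |= c
    rows[_D], c = _row(_D, {_E: tr.tpD2E, _F: tr.tpD2F + overlay},
                       strategy, cycle, age)
    any_clipped |= c
    rows[_E], c = _row(_E, {_F: mor_gp}, strategy, cycle, age)
    any_clipped |= c

    matrix = np.zeros((N_STATES, N_STATES))
    for idx, row in rows.items():
        matrix[idx] = row
    matrix[_F, _F] = 1.0
    return TransitionMatrix(matrix=matrix, strategy=strategy, cycle=cycle,
                            age=age, clipped=any_clipped)


def dump_matrices(params: ModelParameters, lifetable: LifeTable):
    """All horizon x strategy matrices as a tidy DataFrame (audit export)."""
    import pandas as pd

    rows = []
    for strategy in Strategy:
        for cycle in range(params.horizon_cycles):
            age = params.entry_age + cycle
            tm = build_matrix(strategy, cycle, age, params, lifetable)
            for i, frm in enumerate("ABCDEF"):
                for j, to in enumerate("ABCDEF"):
                    if STRUCTURE_MASK[i, j]:
                        rows.append(
                            {
                                "strategy": strategy.value,
                                "cycle": cycle,
                                "age": age,
                                "from": frm,
                                "to": to,
                                "p": tm.matrix[i, j],
                            }
                        )
    return pd.DataFrame(rows)
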