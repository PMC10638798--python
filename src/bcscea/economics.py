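"""Incremental cost-effectiveness analysis with dominance elimination.

Strategies are ranked by effectiveness; strategies that are more costly and
no more effective than an alternative are strongly dominated, and strategies
whose incremental cost-effectiveness ratio (ICER) exceeds that of the next
more effective option are extendedly dominated (a mix of the neighbours
would buy their benefit more cheaply).  ICERs between adjacent survivors on
the efficiency frontier are classified against the Swedish willingness-to-pay
bands: < 100,000 SEK/QALY low; 100,000-499,999 moderate; 500,000-1,000,000
high; above 1 million very high.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import AnalysisError, ParameterError
from .states import Strategy
from .engine import StrategyResult

__all__ = ["icer", "categorize_icer", "incremental_analysis",
           "analyse_points", "CEAResult",
           "DOMINANCE_NONE", "DOMINANCE_STRONG", "DOMINANCE_EXTENDED"]

DOMINANCE_NONE = "none"
DOMINANCE_STRONG = "strongly_dominated"
DOMINANCE_EXTENDED = "extendedly_dominated"


def icer(cost_a: float, qaly_a: float, cost_b: float, qaly_b: float) -> float:
    """Incremental cost-effectiveness ratio of A over B (SEK per QALY)."""
    if qaly_a == qaly_b:
        raise AnalysisError(
            "ICER undefined for equal effectiveness "
            f"(both at {qaly_a} QALYs); resolve by dominance instead"
        )
    return (cost_a - cost_b) / (qaly_a - qaly_b)


def categorize_icer(icer_value: float) -> str:
    """Swedish cost-per-QALY band of a (non-negative) frontier ICER."""
    if icer_value < 0:
        raise ParameterError(
            f"negative ICER {icer_value}; dominated strategies must be "
            "excluded before categorisation"
        )
    if icer_value < 100_000:
        return "low"
    if icer_value < 500_000:
        return "moderate"
    if icer_value <= 1_000_000:
        return "high"
    return "very_high"


@dataclass
class CEAResult:
    """Outcome of an incremental analysis for one perspective.

    ``frontier`` lists the non-dominated strategies in increasing order of
    cost and QALY; ``icers`` holds the ICER between each frontier strategy
    and its cheaper neighbour (keyed by the more effective strategy), with
    the matching Swedish band in ``categories``.
    """

    perspective: str
    cost: dict[Strategy, float]
    qaly: dict[Strategy, float]
    average_ce_ratio: dict[Strategy, float]
    dominance: dict[Strategy, str]
    frontier: list[Strategy]
    icers: dict[Strategy, float]
    categories: dict[Strategy, str]

    def to_frame(self) -> pd.DataFrame:
        """Results-table export (one row per strategy)."""
        rows = []
        for strat in self.cost:
            rows.append(
                {
                    "strategy": strat.value,
                    "qaly": self.qaly[strat],
                    "cost": self.cost[strat],
                    "average_ce_ratio": self.average_ce_ratio[strat],
                    "dominance": self.dominance[strat],
                    "icer_vs_next_cheaper": self.icers.get(strat),
                    "icer_category": self.categories.get(strat),
                    "perspective": self.perspective,
                }
            )
        return pd.DataFrame(rows)


def incremental_analysis(
    results: Iterable[StrategyResult] | dict[Strategy, StrategyResult],
    perspective: str = "healthcare",
) -> CEAResult:
    """Full incremental analysis: dominance labels, frontier, ICERs, bands.

    Independent of input ordering.  Requires at least two strategies.
    """
    if isinstance(results, dict):
        results = list(results.values())
    else:
        results = list(results)
    if len(results) < 2:
        raise AnalysisError(
            f"incremental analysis needs >= 2 strategies, got {len(results)}"
        )
    cost = {r.strategy: r.cost(perspective) for r in results}
    qaly = {r.strategy: r.qaly for r in results}
    return analyse_points(cost, qaly, perspective)


def analyse_points(
    cost: dict, qaly: dict, perspective: str = "healthcare"
) -> CEAResult:
    """Incremental analysis on bare (cost, QALY) points keyed by strategy.

    Same algorithm as :func:`incremental_analysis`; the keys may be any
    hashable labels, which makes this the natural entry point for analysing
    PSA means or synthetic test instances.
    """
    if len(cost) < 2:
        raise AnalysisError(
            f"incremental analysis needs >= 2 strategies, got {len(cost)}"
        )
    average = {
        s: (cost[s] / qaly[s]) if qaly[s] > 0 else float("inf") for s in cost
    }
    dominance = {s: DOMINANCE_NONE for s in cost}

    # strong dominance: more costly and no more effective than some
    # alternative (ties on QALY resolved in favour of the cheaper strategy).
    for s in cost:
        for other in cost:
            if other is s:
                continue
            if (qaly[other] >= qaly[s] and cost[other] < cost[s]) or (
                qaly[other] > qaly[s] and cost[other] <= cost[s]
            ):
                dominance[s] = DOMINANCE_STRONG
                break

    # extended dominance: with survivors sorted by effectiveness, remove any
    # strategy whose ICER over its cheaper neighbour exceeds the next ICER
    # up the ladder, until the ICER sequence is increasing.
    frontier = sorted(
        (s for s in cost if dominance[s] == DOMINANCE_NONE),
        key=lambda s: (qaly[s], cost[s]),
    )
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            below, here, above = frontier[i - 1], frontier[i], frontier[i + 1]
            # ICER(below->here) > ICER(here->above), compared by
            # cross-multiplication (QALY gaps are positive after sorting)
            # with a relative tolerance so exactly collinear strategies are
            # kept rather than dropped on float noise.
            lhs = (cost[here] - cost[below]) * (qaly[above] - qaly[here])
            rhs = (cost[above] - cost[here]) * (qaly[here] - qaly[below])
            if lhs > rhs + 1e-9 * max(abs(lhs), abs(rhs), 1.0):
                dominance[here] = DOMINANCE_EXTENDED
                frontier.pop(i)
                changed = True
                break

    icers = {}
    categories = {}
    for prev, nxt in zip(frontier, frontier[1:]):
        value = icer(cost[nxt], qaly[nxt], cost[prev], qaly[prev])
        icers[nxt] = value
        categories[nxt] = categorize_icer(value)
    return CEAResult(
        perspective=perspective,
        cost=cost,
        qaly=qaly,
        average_ce_ratio=average,
        dominance=dominance,
        frontier=frontier,
        icers=icers,
        categories=categories,
    )
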