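"""Probabilistic sensitivity analysis (Monte Carlo over parameter uncertainty).

Every uncertain parameter is sampled from its published distribution — Beta
for probabilities and utilities, Gamma (shape, scale) for costs, truncated
Normal for entry age — and the cohort model is re-run for all three
strategies on each draw with common random parameters (so arms are compared
within a simulation).  Parameters the evidence table marks as not applicable
(background mortality, discount rates, societal add-ons, complements) stay
at their deterministic values; complements are recomputed per draw and
draws whose exit probabilities exceed one are rejected and resampled.

Recurrence uncertainty: the evidence table supplies a single Beta for the
time- and strategy-dependent cancer-free -> recurrence probability despite
nine deterministic values.  We sample one multiplicative shift — the drawn
probability divided by the Beta's mean — and scale all nine period
incidences by it, preserving the published between-strategy and
between-period structure.  This scheme is this package's construction.

Outputs: per-draw (cost, QALY) per strategy and perspective, summary means
and percentile intervals, an incremental analysis on the PSA means,
cost-effectiveness planes, and CEAC curves based on net monetary benefit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import CEAResult, analyse_points
from .engine import run_cohort
from .errors import AnalysisError, ParameterError, ValidationError
from .parameters import ModelParameters, PSADistributionSpec
from .states import Strategy
from .synthetic_data import LifeTable

__all__ = ["sample_draw", "run_psa", "ceac", "PSAResult", "CEACCurve",
           "DEFAULT_WTP_GRID"]

logger = logging.getLogger(__name__)

#: default willingness-to-pay grid, 0 to 2 million SEK/QALY in 100k steps.
DEFAULT_WTP_GRID = np.arange(0, 2_000_001, 100_000)

_AGE_BOUNDS = (18, 100)
_MAX_REJECTIONS = 1000

_TP_NAMES = ("tpA2D", "tpB2C", "tpB2F", "tpC2D", "tpD2E", "tpD2F")
_COST_SETTERS = {
    "cam": ("baseline_cost", Strategy.MASTECTOMY),
    "cal_wo": ("baseline_cost", Strategy.LUMPECTOMY_NO_RT),
    "cal_w": ("baseline_cost", Strategy.LUMPECTOMY_RT),
    "cbm": ("stateB_cost", Strategy.MASTECTOMY),
    "cbl": ("stateB_cost", None),  # both lumpectomy arms share one draw
    "cd": ("stateD_cost", None),
}
_UTILITY_SETTERS = {
    "uam": ("state_a", Strategy.MASTECTOMY),
    "ual": ("state_a", None),  # both lumpectomy arms share one draw
    "ub": ("ub", None),
    "uc": ("uc", None),
    "ud": ("ud", None),
    "ue": ("ue", None),
}


def _sample_value(spec: PSADistributionSpec, rng: np.random.Generator) -> float:
    if spec.family == "beta":
        a, b = spec.params
        return float(rng.beta(a, b))
    if spec.family == "gamma":
        shape, scale = spec.params
        return float(rng.gamma(shape, scale))
    if spec.family == "normal":
        mean, sd = spec.params
        return float(rng.normal(mean, sd))
    raise ParameterError(f"cannot sample fixed spec {spec.name!r}")


def sample_draw(
    specs: list[PSADistributionSpec],
    rng: np.random.Generator,
    base: ModelParameters,
) -> tuple[ModelParameters, dict[str, float]]:
    """One joint parameter draw applied to a copy of ``base``.

    Returns the perturbed parameter set and the raw sampled values by
    parameter name.  Draws that violate row feasibility (paired exit
    probabilities summing above one) are rejected and redrawn, up to
    ``_MAX_REJECTIONS`` consecutive failures.
    """
    by_name = {spec.name: spec for spec in specs if spec.family != "fixed"}
    for attempt in range(_MAX_REJECTIONS):
        params = base.copy()
        sampled: dict[str, float] = {}

        if "age" in by_name:
            lo, hi = _AGE_BOUNDS
            age = _sample_value(by_name["age"], rng)
            while not lo <= age <= hi:
                age = _sample_value(by_name["age"], rng)
            params.entry_age = int(round(age))
            sampled["age"] = float(params.entry_age)

        for name in _TP_NAMES:
            if name in by_name:
                value = _sample_value(by_name[name], rng)
                setattr(params.transitions, name, value)
                sampled[name] = value

        if "tpA2B" in by_name:
            spec = by_name["tpA2B"]
            draw = _sample_value(spec, rng)
            shift = draw / spec.mean
            sampled["tpA2B"] = draw
            sampled["tpA2B_shift"] = shift
            for strat, schedule in params.transitions.recurrence_schedules.items():
                params.transitions.recurrence_schedules[strat] = (
                    schedule.scaled(shift)
                )

        for name, (attr, strat) in _COST_SETTERS.items():
            if name in by_name:
                value = _sample_value(by_name[name], rng)
                sampled[name] = value
                target = getattr(params.costs, attr)
                if strat is not None:
                    target[strat] = value
                elif attr == "stateB_cost":
                    target[Strategy.LUMPECTOMY_NO_RT] = value
                    target[Strategy.LUMPECTOMY_RT] = value
                else:
                    setattr(params.costs, attr, value)

        for name, (attr, strat) in _UTILITY_SETTERS.items():
            if name in by_name:
                value = _sample_value(by_name[name], rng)
                sampled[name] = value
                if strat is not None:
                    params.utilities.state_a[strat] = value
                elif attr == "state_a":
                    params.utilities.state_a[Strategy.LUMPECTOMY_NO_RT] = value
                    params.utilities.state_a[Strategy.LUMPECTOMY_RT] = value
                else:
                    setattr(params.utilities, attr, value)

        tr = params.transitions
        feasible = (
            tr.tpB2C + tr.tpB2F <= 1.0 and tr.tpD2E + tr.tpD2F <= 1.0
        )
        if feasible:
            return params, sampled
        logger.debug("rejected infeasible draw (attempt %d)", attempt + 1)
    raise AnalysisError(
        f"{_MAX_REJECTIONS} consecutive infeasible PSA draws; check the "
        "distribution specs"
    )


@dataclass
class CEACCurve:
    """Probability one strategy is cost-effective vs another over WTP values."""

    comparison: str
    perspective: str
    wtp: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wtp": self.wtp,
                "probability": self.probability,
                "comparison": self.comparison,
                "perspective": self.perspective,
            }
        )


@dataclass
class PSAResult:
    """Per-draw results plus summaries.

    ``draws`` is a tidy DataFrame with one row per iteration carrying the
    sampled parameter values and per-strategy discounted cost (both
    perspectives) and QALYs.
    """

    draws: pd.DataFrame
    n_iter: int
    seed: int | None

    def _col(self, strategy: Strategy, quantity: str) -> pd.Series:
        return self.draws[f"{quantity}_{strategy.value}"]

    def qalys(self, strategy: Strategy) -> np.ndarray:
        return self._col(strategy, "qaly").to_numpy()

    def costs(self, strategy: Strategy,
              perspective: str = "healthcare") -> np.ndarray:
        key = "cost_hc" if perspective == "healthcare" else "cost_soc"
        return self._col(strategy, key).to_numpy()

    def mean_qaly(self, strategy: Strategy) -> float:
        return float(self.qalys(strategy).mean())

    def mean_cost(self, strategy: Strategy,
                  perspective: str = "healthcare") -> float:
        return float(self.costs(strategy, perspective).mean())

    def interval(self, values: np.ndarray,
                 level: float = 0.95) -> tuple[float, float]:
        """Empirical central interval (2.5th/97.5th percentiles by default)."""
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
        return float(lo), float(hi)

    def summary(self) -> pd.DataFrame:
        """Per-strategy means and 95% percentile intervals."""
        rows = []
        for strat in Strategy:
            q = self.qalys(strat)
            row = {"strategy": strat.value,
                   "mean_qaly": q.mean(),
                   "qaly_lo": self.interval(q)[0],
                   "qaly_hi": self.interval(q)[1]}
            for perspective, tag in (("healthcare", "hc"), ("societal", "soc")):
                c = self.costs(strat, perspective)
                row[f"mean_cost_{tag}"] = c.mean()
                row[f"cost_{tag}_lo"] = self.interval(c)[0]
                row[f"cost_{tag}_hi"] = self.interval(c)[1]
            rows.append(row)
        return pd.DataFrame(rows)

    def incremental_on_means(self, perspective: str = "healthcare") -> CEAResult:
        """Incremental analysis of the PSA mean (cost, QALY) per strategy."""
        cost = {s: self.mean_cost(s, perspective) for s in Strategy}
        qaly = {s: self.mean_qaly(s) for s in Strategy}
        return analyse_points(cost, qaly, perspective)

    def ce_plane(self, alternative: Strategy, comparator: Strategy,
                 perspective: str = "healthcare") -> pd.DataFrame:
        """Incremental (QALY, cost) cloud of ``alternative`` vs ``comparator``."""
        return pd.DataFrame(
            {
                "delta_qaly": self.qalys(alternative) - self.qalys(comparator),
                "delta_cost": (self.costs(alternative, perspective)
                               - self.costs(comparator, perspective)),
            }
        )


def run_psa(
    params: ModelParameters,
    lifetable: LifeTable,
    n_iter: int = 1000,
    seed: int | None = None,
) -> PSAResult:
    """Monte Carlo PSA: ``n_iter`` joint draws, three cohort runs per draw."""
    if n_iter < 1:
        raise ParameterError(f"n_iter must be >= 1, got {n_iter}")
    params.validate()
    rng = np.random.default_rng(seed)
    rows = []
    clipped_draws = 0
    for iteration in range(n_iter):
        draw_params, sampled = sample_draw(params.psa_specs, rng, params)
        row: dict[str, float] = {"iteration": iteration, **sampled}
        clipped = False
        try:
            for strat in Strategy:
                result = run_cohort(strat, draw_params, lifetable)
                row[f"qaly_{strat.value}"] = result.qaly
                row[f"cost_hc_{strat.value}"] = result.cost_healthcare
                row[f"cost_soc_{strat.value}"] = result.cost_societal
                clipped |= result.trace.clipped_cycles > 0
        except Exception:
            logger.error("PSA iteration %d failed (seed=%r)", iteration, seed)
            raise
        clipped_draws += clipped
        rows.append(row)
    if clipped_draws:
        logger.warning(
            "transition rows clipped (death capped at 1) in %d of %d PSA "
            "draws, at extreme sampled entry ages",
            clipped_draws, n_iter,
        )
    return PSAResult(draws=pd.DataFrame(rows), n_iter=n_iter, seed=seed)


def ceac(
    psa: PSAResult,
    alternative: Strategy,
    comparator: Strategy,
    wtp_grid: np.ndarray | None = None,
    perspective: str = "healthcare",
) -> CEACCurve:
    """Cost-effectiveness acceptability curve of ``alternative`` vs ``comparator``.

    For each willingness-to-pay value w the curve gives the fraction of
    draws in which the alternative has the higher net monetary benefit
    ``NMB = w * QALY - cost``.
    """
    if wtp_grid is None:
        wtp_grid = DEFAULT_WTP_GRID
    wtp = np.asarray(wtp_grid, dtype=float)
    if wtp.size == 0:
        raise ParameterError("empty willingness-to-pay grid")
    if np.any(np.diff(wtp) <= 0):
        raise ParameterError("willingness-to-pay grid must be strictly increasing")
    if psa.draws.empty:
        raise AnalysisError("no PSA draws to build a CEAC from")
    dq = psa.qalys(alternative) - psa.qalys(comparator)
    dc = psa.costs(alternative, perspective) - psa.costs(comparator, perspective)
    nmb = wtp[:, None] * dq[None, :] - dc[None, :]
    return CEACCurve(
        comparison=f"{alternative.value}_vs_{comparator.value}",
        perspective=perspective,
        wtp=wtp,
        probability=(nmb > 0).mean(axis=1),
    )
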