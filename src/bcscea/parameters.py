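"""Typed model parameters, packaged base-case values and YAML config I/O.

All monetary amounts are 2020 Swedish krona (SEK); probabilities and utility
weights are annual/per-cycle quantities on a one-year cycle.  Config files use
the short parameter names of the published parameter table (``cam``,
``cal_wo``, ``tpA2D`` ...) so the table maps one-to-one onto the file; any key
left out of a config falls back to the packaged base case.
"""

from __future__ import annotations

import copy
import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .errors import ConfigurationError, ValidationError
from .states import Strategy

# ---------------------------------------------------------------------------
# recurrence schedule (time-dependent A -> B incidence)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecurrenceSchedule:
    """Piecewise-constant loco-regional recurrence incidence.

    ``periods`` is an ordered list of ``(start_year, end_year, rate)`` with
    half-open follow-up windows (``start`` inclusive, ``end`` exclusive) and
    rates in events per 1000 person-years.  The packaged schedules use the
    windows [0,5), [5,10), [10,30).
    """

    periods: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.periods:
            raise ValidationError("RecurrenceSchedule.periods must be non-empty")
        prev_end = None
        prev_rate = None
        for start, end, rate in self.periods:
            if end <= start:
                raise ValidationError(
                    f"RecurrenceSchedule window [{start}, {end}) is empty"
                )
            if prev_end is not None and not math.isclose(start, prev_end):
                raise ValidationError(
                    f"RecurrenceSchedule windows must be contiguous; "
                    f"gap/overlap at year {start}"
                )
            if rate < 0:
                raise ValidationError(
                    f"RecurrenceSchedule rate {rate} in window [{start}, {end}) "
                    "is negative"
                )
            if prev_rate is not None and rate > prev_rate + 1e-12:
                raise ValidationError(
                    "RecurrenceSchedule rates must be non-increasing across "
                    f"windows (got {prev_rate} then {rate})"
                )
            prev_end, prev_rate = end, rate

    @property
    def start(self) -> float:
        return self.periods[0][0]

    @property
    def end(self) -> float:
        return self.periods[-1][1]

    def rate_at(self, year: float) -> float:
        """Incidence (per 1000 PY) of the window containing ``year``."""
        for start, end, rate in self.periods:
            if start <= year < end:
                return rate
        raise ValidationError(
            f"year {year} outside schedule coverage [{self.start}, {self.end})"
        )

    def scaled(self, factor: float) -> "RecurrenceSchedule":
        """Schedule with every rate multiplied by ``factor``."""
        return RecurrenceSchedule(
            tuple((s, e, r * factor) for s, e, r in self.periods)
        )


# ---------------------------------------------------------------------------
# grouped inputs
# ---------------------------------------------------------------------------


@dataclass
class TransitionInputs:
    """Annual transition probabilities and their evidence base.

    The six scalar probabilities are the cumulative-incidence-derived inputs
    of the parameter table; ``source_cis`` keeps the (cumulative incidence,
    follow-up years) pair each was derived from, so they can be re-derived
    with :func:`bcscea.transitions.prob_from_cumulative_incidence`.  The
    strategy-specific cancer-free -> recurrence input lives in
    ``recurrence_schedules`` as raw incidences.
    """

    tpA2D: float = 0.008
    tpB2C: float = 0.165
    tpB2F: float = 0.065
    tpC2D: float = 0.230
    tpD2E: float = 0.375
    tpD2F: float = 0.178
    source_cis: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "tpA2D": (0.143, 20.0),
            "tpB2C": (0.763, 8.0),
            "tpB2F": (0.49, 10.0),
            "tpC2D": (0.73, 5.0),
            "tpD2E": (0.609, 2.0),
            "tpD2F": (0.86, 10.0),
        }
    )
    recurrence_schedules: dict[Strategy, RecurrenceSchedule] = field(
        default_factory=lambda: {
            Strategy.MASTECTOMY: RecurrenceSchedule(
                ((0, 5, 56.46), (5, 10, 26.77), (10, 30, 7.09))
            ),
            Strategy.LUMPECTOMY_NO_RT: RecurrenceSchedule(
                ((0, 5, 71.70), (5, 10, 34.00), (10, 30, 9.00))
            ),
            Strategy.LUMPECTOMY_RT: RecurrenceSchedule(
                ((0, 5, 36.90), (5, 10, 24.30), (10, 30, 8.30))
            ),
        }
    )
    #: incidence-rate ratio mastectomy : lumpectomy-without-irradiation used
    #: to transfer the mastectomy recurrence schedule from trial evidence.
    irr_mastectomy_vs_lump_no_rt: float = 1.27

    def validate(self) -> None:
        for name in ("tpA2D", "tpB2C", "tpB2F", "tpC2D", "tpD2E", "tpD2F"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} = {value} outside [0, 1]")
        if self.tpB2C + self.tpB2F > 1.0:
            raise ValidationError(
                f"tpB2C + tpB2F = {self.tpB2C + self.tpB2F} > 1 "
                "(stay-probability tpB2B would be negative)"
            )
        if self.tpD2E + self.tpD2F > 1.0:
            raise ValidationError(
                f"tpD2E + tpD2F = {self.tpD2E + self.tpD2F} > 1 "
                "(stay-probability tpD2D would be negative)"
            )
        if self.irr_mastectomy_vs_lump_no_rt <= 0:
            raise ValidationError(
                "irr_mastectomy_vs_lump_no_rt must be positive, got "
                f"{self.irr_mastectomy_vs_lump_no_rt}"
            )
        missing = set(Strategy) - set(self.recurrence_schedules)
        if missing:
            raise ValidationError(
                f"recurrence schedule missing for {sorted(s.value for s in missing)}"
            )


@dataclass
class CostInputs:
    """Cost parameters (2020 SEK).

    ``baseline_cost`` is the average surgery + hospitalisation cost of each
    arm; it is charged once on model entry and, matching the published
    totals, also accrues for every cycle spent cancer-free (see the engine
    documentation).  ``stateB_cost``/``stateD_cost`` are per-cycle costs of
    the recurrence and metastasis states; remission and death are costless.
    """

    baseline_cost: dict[Strategy, float] = field(
        default_factory=lambda: {
            Strategy.MASTECTOMY: 87_670.0,
            Strategy.LUMPECTOMY_NO_RT: 27_655.0,
            Strategy.LUMPECTOMY_RT: 50_352.0,
        }
    )
    stateB_cost: dict[Strategy, float] = field(
        default_factory=lambda: {
            Strategy.MASTECTOMY: 17_680.0,
            Strategy.LUMPECTOMY_NO_RT: 87_670.0,
            Strategy.LUMPECTOMY_RT: 87_670.0,
        }
    )
    stateD_cost: float = 499_343.0
    #: annual informal-care + transport cost (societal perspective); halved
    #: for lumpectomy without irradiation (shorter hospitalisation).
    informal_care: dict[Strategy, float] = field(
        default_factory=lambda: {
            Strategy.MASTECTOMY: 10_003.0,
            Strategy.LUMPECTOMY_NO_RT: 5_002.0,
            Strategy.LUMPECTOMY_RT: 10_003.0,
        }
    )
    #: annual productivity gained by lumpectomy arms vs mastectomy,
    #: first ``productivity_years`` follow-up years (societal perspective).
    productivity_gain: float = 4_104.0
    productivity_years: int = 10
    #: Swedish DRG reference cost for lumpectomy without irradiation, used to
    #: split the registry's pooled lumpectomy arm.
    drg_lumpectomy_no_rt_reference: float = 36_439.0

    def validate(self) -> None:
        for name in ("baseline_cost", "stateB_cost", "informal_care"):
            mapping = getattr(self, name)
            missing = set(Strategy) - set(mapping)
            if missing:
                raise ValidationError(
                    f"{name} missing entries for {sorted(s.value for s in missing)}"
                )
            for strat, value in mapping.items():
                if value < 0:
                    raise ValidationError(
                        f"{name}[{strat.value}] = {value} is negative"
                    )
        for name in ("stateD_cost", "productivity_gain",
                     "drg_lumpectomy_no_rt_reference"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} = {getattr(self, name)} is negative")


@dataclass
class UtilityInputs:
    """Health-state utility weights in [0, 1]; death is worth 0.

    The remission weights are the published scalars 0.81 (C) and 0.76 (E) for
    every arm.  The source table motivates them as averages of the adjacent
    states, which is exact only for the mastectomy arm; the printed scalars
    are used as-is and never re-derived.
    """

    state_a: dict[Strategy, float] = field(
        default_factory=lambda: {
            Strategy.MASTECTOMY: 0.84,
            Strategy.LUMPECTOMY_NO_RT: 0.87,
            Strategy.LUMPECTOMY_RT: 0.87,
        }
    )
    ub: float = 0.78
    uc: float = 0.81
    ud: float = 0.69
    ue: float = 0.76
    death: float = 0.0

    def weights_for(self, strategy: Strategy) -> tuple[float, ...]:
        """Utility vector (A..F) for one strategy."""
        return (self.state_a[strategy], self.ub, self.uc, self.ud, self.ue,
                self.death)

    def validate(self) -> None:
        missing = set(Strategy) - set(self.state_a)
        if missing:
            raise ValidationError(
                f"state_a utility missing for {sorted(s.value for s in missing)}"
            )
        items = [(f"state_a[{s.value}]", v) for s, v in self.state_a.items()]
        items += [(n, getattr(self, n)) for n in ("ub", "uc", "ud", "ue", "death")]
        for name, value in items:
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"utility {name} = {value} outside [0, 1]")


@dataclass
class DiscountRates:
    """Annual discount rates for costs (cDR) and outcomes (oDR)."""

    cost_rate: float = 0.03
    outcome_rate: float = 0.03

    def validate(self) -> None:
        for name in ("cost_rate", "outcome_rate"):
            value = getattr(self, name)
            if not 0.0 <= value < 1.0:
                raise ValidationError(f"{name} = {value} outside [0, 1)")


@dataclass(frozen=True)
class PSADistributionSpec:
    """Sampling distribution of one uncertain parameter.

    ``family`` is one of ``beta`` (params = alpha, beta), ``gamma``
    (params = shape, scale — shape x scale reproduces the deterministic
    mean), ``normal`` (params = mean, sd) or ``fixed``.
    """

    name: str
    family: str
    params: tuple[float, ...] = ()

    _FAMILIES = ("beta", "gamma", "normal", "fixed")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ValidationError(
                f"unknown distribution family {self.family!r} for "
                f"{self.name!r}; expected one of {self._FAMILIES}"
            )
        if self.family in ("beta", "gamma"):
            if len(self.params) != 2 or min(self.params) <= 0:
                raise ValidationError(
                    f"{self.name}: {self.family} needs two strictly positive "
                    f"shape parameters, got {self.params}"
                )
        if self.family == "normal" and len(self.params) != 2:
            raise ValidationError(
                f"{self.name}: normal needs (mean, sd), got {self.params}"
            )

    @property
    def mean(self) -> float:
        if self.family == "beta":
            a, b = self.params
            return a / (a + b)
        if self.family == "gamma":
            shape, scale = self.params
            return shape * scale
        if self.family == "normal":
            return self.params[0]
        raise ValidationError(f"{self.name}: fixed spec has no implied mean")


def default_psa_specs() -> list[PSADistributionSpec]:
    """The published sampling distributions of all uncertain parameters.

    Parameters marked not-applicable in the source table (background
    mortality, discount rates, societal add-ons, complements) are held fixed
    in the PSA and therefore carry no spec here.
    """
    spec = PSADistributionSpec
    return [
        spec("age", "normal", (58.0, 11.8)),
        # a single Beta governs the nine period/strategy recurrence values via
        # a common multiplicative shift (see bcscea.psa).
        spec("tpA2B", "beta", (54.84, 944.16)),
        spec("tpA2D", "beta", (7.70, 991.30)),
        spec("tpB2C", "beta", (164.52, 834.48)),
        spec("tpB2F", "beta", (65.05, 933.95)),
        spec("tpC2D", "beta", (230.16, 768.84)),
        spec("tpD2E", "beta", (374.33, 624.67)),
        spec("tpD2F", "beta", (178.31, 820.69)),
        spec("cam", "gamma", (656.50, 133.54)),
        spec("cal_wo", "gamma", (4_253.80, 6.50)),
        spec("cal_w", "gamma", (6_217.04, 8.10)),
        spec("cbm", "gamma", (26.70, 662.20)),
        spec("cbl", "gamma", (42_749.59, 2.05)),
        spec("cd", "gamma", (1_386_844.91, 0.36)),
        spec("uam", "beta", (839.16, 159.84)),
        spec("ual", "beta", (869.13, 129.87)),
        spec("ub", "beta", (778.22, 220.78)),
        spec("uc", "beta", (808.69, 190.31)),
        spec("ud", "beta", (684.32, 314.69)),
        spec("ue", "beta", (761.74, 237.26)),
    ]


# ---------------------------------------------------------------------------
# top-level parameter set
# ---------------------------------------------------------------------------

PERSPECTIVES = ("healthcare", "societal")
INFORMAL_CARE_SCOPES = ("flat_annuity", "state_D", "all_alive")


@dataclass
class ModelParameters:
    """Complete parameterisation of one model run."""

    entry_age: int = 58
    horizon_cycles: int = 30
    cycle_length: float = 1.0
    transitions: TransitionInputs = field(default_factory=TransitionInputs)
    costs: CostInputs = field(default_factory=CostInputs)
    utilities: UtilityInputs = field(default_factory=UtilityInputs)
    discount: DiscountRates = field(default_factory=DiscountRates)
    psa_specs: list[PSADistributionSpec] = field(default_factory=default_psa_specs)
    perspective: str = "healthcare"

    # --- accrual conventions (see docs/methods.md) --------------------------
    #: charge the arm baseline cost once on entry (cycle 0, undiscounted).
    charge_entry_cost: bool = True
    #: additionally charge the baseline cost per cycle spent cancer-free;
    #: required to reproduce the published cost totals.
    state_a_running_cost: bool = True
    #: how the societal informal-care cost accrues: a flat discounted annuity
    #: over the horizon (matches the published increments), per cycle in the
    #: metastatic state, or per cycle alive.
    informal_care_scope: str = "flat_annuity"
    #: weight the productivity-gain annuity by the probability of being alive
    #: instead of a flat 10-year annuity.
    productivity_alive_weighted: bool = False
    #: add background mortality to the disease-specific death exits of the
    #: recurrence/metastasis states (as published) rather than treating those
    #: exits as all-cause.
    background_mortality_additive: bool = True
    #: half-cycle correction (off: the source model shows no sign of one).
    half_cycle_correction: bool = False

    def validate(self) -> "ModelParameters":
        if self.horizon_cycles < 1:
            raise ValidationError(
                f"horizon_cycles = {self.horizon_cycles} must be >= 1"
            )
        if self.cycle_length <= 0:
            raise ValidationError(f"cycle_length = {self.cycle_length} must be > 0")
        if not 0 <= self.entry_age <= 110:
            raise ValidationError(f"entry_age = {self.entry_age} implausible")
        if self.perspective not in PERSPECTIVES:
            raise ValidationError(
                f"perspective {self.perspective!r} not in {PERSPECTIVES}"
            )
        if self.informal_care_scope not in INFORMAL_CARE_SCOPES:
            raise ValidationError(
                f"informal_care_scope {self.informal_care_scope!r} not in "
                f"{INFORMAL_CARE_SCOPES}"
            )
        self.transitions.validate()
        self.costs.validate()
        self.utilities.validate()
        self.discount.validate()
        horizon_end = self.transitions.recurrence_schedules[
            Strategy.MASTECTOMY
        ].end
        if self.horizon_cycles > horizon_end:
            raise ValidationError(
                f"horizon_cycles = {self.horizon_cycles} exceeds recurrence "
                f"schedule coverage ({horizon_end} years)"
            )
        return self

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)


def default_parameters() -> ModelParameters:
    """The packaged base case (healthcare perspective, 2020 SEK)."""
    return ModelParameters().validate()


def default_config_path() -> Path:
    """Path of the packaged base-case YAML (a template for custom configs)."""
    return Path(__file__).parent / "data" / "default_config.yaml"


# ---------------------------------------------------------------------------
# YAML config I/O
# ---------------------------------------------------------------------------

_STRATEGY_KEYS = {
    "mastectomy": Strategy.MASTECTOMY,
    "lumpectomy_no_rt": Strategy.LUMPECTOMY_NO_RT,
    "lumpectomy_rt": Strategy.LUMPECTOMY_RT,
}

_TP_KEYS = ("tpA2D", "tpB2C", "tpB2F", "tpC2D", "tpD2E", "tpD2F")
_COST_KEYS = {  # short name -> (attribute, strategy or None)
    "cam": ("baseline_cost", Strategy.MASTECTOMY),
    "cal_wo": ("baseline_cost", Strategy.LUMPECTOMY_NO_RT),
    "cal_w": ("baseline_cost", Strategy.LUMPECTOMY_RT),
    "cbm": ("stateB_cost", Strategy.MASTECTOMY),
    "cbl_wo": ("stateB_cost", Strategy.LUMPECTOMY_NO_RT),
    "cbl_w": ("stateB_cost", Strategy.LUMPECTOMY_RT),
    "cd": ("stateD_cost", None),
    "infocare_m": ("informal_care", Strategy.MASTECTOMY),
    "infocare_l_wo": ("informal_care", Strategy.LUMPECTOMY_NO_RT),
    "infocare_l_w": ("informal_care", Strategy.LUMPECTOMY_RT),
    "prod": ("productivity_gain", None),
    "drg_lump_no_rt": ("drg_lumpectomy_no_rt_reference", None),
}
_UTILITY_KEYS = {
    "uam": ("state_a", Strategy.MASTECTOMY),
    "ual_wo": ("state_a", Strategy.LUMPECTOMY_NO_RT),
    "ual_w": ("state_a", Strategy.LUMPECTOMY_RT),
    "ub": ("ub", None),
    "uc": ("uc", None),
    "ud": ("ud", None),
    "ue": ("ue", None),
}
_SWITCH_KEYS = (
    "perspective", "charge_entry_cost", "state_a_running_cost",
    "informal_care_scope", "productivity_alive_weighted",
    "background_mortality_additive", "half_cycle_correction",
)


def _number(raw: object, key: str) -> float:
    if isinstance(raw, bool) or not isinstance(raw, (int, float)):
        raise ConfigurationError(f"field {key!r} must be a number, got {raw!r}")
    return float(raw)


def load_parameters(config_path: str | Path) -> ModelParameters:
    """Load a YAML config, fill gaps with the base case, validate.

    Raises :class:`ConfigurationError` for missing/unreadable files or
    malformed fields and :class:`ValidationError` for out-of-range values
    (naming the offending field).
    """
    path = Path(config_path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return parameters_from_dict(raw)


def parameters_from_dict(raw: dict) -> ModelParameters:
    """Build :class:`ModelParameters` from a config mapping (short names)."""
    params = default_parameters()
    known: set[str] = set()

    def take(key: str):
        known.add(key)
        return raw.get(key)

    if (v := take("age")) is not None:
        params.entry_age = int(_number(v, "age"))
    if (v := take("horizon")) is not None:
        params.horizon_cycles = int(_number(v, "horizon"))
    if (v := take("cycle_length")) is not None:
        params.cycle_length = _number(v, "cycle_length")
    for key in _TP_KEYS:
        if (v := take(key)) is not None:
            setattr(params.transitions, key, _number(v, key))
    if (v := take("irr")) is not None:
        params.transitions.irr_mastectomy_vs_lump_no_rt = _number(v, "irr")
    if (v := take("tpA2B")) is not None:
        if not isinstance(v, dict):
            raise ConfigurationError(
                "field 'tpA2B' must map strategy -> [[start, end, rate], ...]"
            )
        for skey, periods in v.items():
            if skey not in _STRATEGY_KEYS:
                raise ConfigurationError(f"unknown strategy {skey!r} in tpA2B")
            try:
                schedule = RecurrenceSchedule(
                    tuple((float(s), float(e), float(r)) for s, e, r in periods)
                )
            except (TypeError, ValueError) as exc:
                raise ConfigurationError(
                    f"malformed tpA2B schedule for {skey}: {exc}"
                ) from exc
            params.transitions.recurrence_schedules[_STRATEGY_KEYS[skey]] = schedule
    # table short names covering both lumpectomy arms at once
    if (v := take("cbl")) is not None:
        value = _number(v, "cbl")
        for strat in (Strategy.LUMPECTOMY_NO_RT, Strategy.LUMPECTOMY_RT):
            params.costs.stateB_cost[strat] = value
    if (v := take("infocare")) is not None:
        value = _number(v, "infocare")
        params.costs.informal_care[Strategy.MASTECTOMY] = value
        params.costs.informal_care[Strategy.LUMPECTOMY_RT] = value
        params.costs.informal_care[Strategy.LUMPECTOMY_NO_RT] = value / 2.0
    for key, (attr, strat) in _COST_KEYS.items():
        if (v := take(key)) is not None:
            value = _number(v, key)
            if strat is None:
                setattr(params.costs, attr, value)
            else:
                getattr(params.costs, attr)[strat] = value
    if (v := take("ual")) is not None:  # both lumpectomy arms share ual
        value = _number(v, "ual")
        for strat in (Strategy.LUMPECTOMY_NO_RT, Strategy.LUMPECTOMY_RT):
            params.utilities.state_a[strat] = value
    for key, (attr, strat) in _UTILITY_KEYS.items():
        if (v := take(key)) is not None:
            value = _number(v, key)
            if strat is None:
                setattr(params.utilities, attr, value)
            else:
                getattr(params.utilities, attr)[strat] = value
    if (v := take("cDR")) is not None:
        params.discount.cost_rate = _number(v, "cDR")
    if (v := take("oDR")) is not None:
        params.discount.outcome_rate = _number(v, "oDR")
    if (v := take("psa")) is not None:
        if not isinstance(v, dict):
            raise ConfigurationError("field 'psa' must map name -> [family, ...]")
        specs = []
        for name, entry in v.items():
            try:
                family, *shape = entry
            except (TypeError, ValueError) as exc:
                raise ConfigurationError(f"malformed psa spec {name!r}") from exc
            specs.append(PSADistributionSpec(name, family, tuple(
                _number(x, f"psa.{name}") for x in shape)))
        params.psa_specs = specs
    for key in _SWITCH_KEYS:
        if (v := take(key)) is not None:
            setattr(params, key, v)

    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
    return params.validate()


def parameters_to_dict(params: ModelParameters) -> dict:
    """Inverse of :func:`parameters_from_dict` (round-trip safe)."""
    tr, co, ut = params.transitions, params.costs, params.utilities
    out: dict = {
        "age": params.entry_age,
        "horizon": params.horizon_cycles,
        "cycle_length": params.cycle_length,
        "irr": tr.irr_mastectomy_vs_lump_no_rt,
        "tpA2B": {
            skey: [list(p) for p in tr.recurrence_schedules[strat].periods]
            for skey, strat in _STRATEGY_KEYS.items()
        },
        "cDR": params.discount.cost_rate,
        "oDR": params.discount.outcome_rate,
        "psa": {
            s.name: [s.family, *s.params] for s in params.psa_specs
        },
    }
    for key in _TP_KEYS:
        out[key] = getattr(tr, key)
    for key, (attr, strat) in _COST_KEYS.items():
        value = getattr(co, attr)
        out[key] = value[strat] if strat is not None else value
    for key, (attr, strat) in _UTILITY_KEYS.items():
        value = getattr(ut, attr)
        out[key] = value[strat] if strat is not None else value
    for key in _SWITCH_KEYS:
        out[key] = getattr(params, key)
    return out


def write_parameters(params: ModelParameters, config_path: str | Path) -> None:
    """Serialise ``params`` to YAML such that ``load_parameters`` round-trips."""
    Path(config_path).write_text(
        yaml.safe_dump(parameters_to_dict(params), sort_keys=False)
    )
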