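"""Synthetic stand-ins for the model's two external data sources.

The original analysis drew on (a) the WHO age-specific all-cause mortality
schedule for the general Swedish population and (b) a confidential
patient-level cost extract from the Swedish National Cancer Registry
(Cancerregistret, in situ cases, 2020).  Neither can be redistributed, so
this module generates statistically similar substitutes:

* :func:`generate_lifetable` — a Gompertz–Makeham mortality schedule whose
  defaults are calibrated to the magnitude of Swedish female mortality
  (q(58) ~ 0.004, q(85) ~ 0.08);
* :func:`generate_registry` — 96 mastectomy + 629 lumpectomy records with
  right-skewed (gamma) per-patient surgery + hospitalisation costs matching
  the published arm means and standard errors.

:func:`read_lifetable` and :func:`read_registry` ingest externally supplied
real versions of either input (plain CSV) for exact reproduction runs.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EstimationError, ParameterError, ValidationError

__all__ = [
    "LifeTable",
    "RegistryRecord",
    "BaselineCostEstimate",
    "generate_lifetable",
    "read_lifetable",
    "generate_registry",
    "read_registry",
    "write_registry",
    "estimate_baseline_costs",
    "inflate",
    "INFLATION_2005_TO_2020",
]

#: CPI factor converting 2005 SEK to 2020 SEK, implied by the published
#: informal-care pair (8,350 SEK in 2005 -> 10,003 SEK in 2020); applying it
#: to the 2005 metastasis cost net of informal care, 425,174 - 8,350,
#: reproduces the packaged State D cost of 499,343 SEK to <0.01%.
INFLATION_2005_TO_2020 = 10_003.0 / 8_350.0

# Published counts of the in situ registry extract.
REGISTRY_N_MASTECTOMY = 96
REGISTRY_N_LUMPECTOMY = 629
REGISTRY_N_LUMPECTOMY_RT = 389
REGISTRY_FRAC_LUMP_RT = REGISTRY_N_LUMPECTOMY_RT / REGISTRY_N_LUMPECTOMY

# Published per-arm cost means and standard errors (2020 SEK) at the counts
# above; the generator's gamma components are moment-matched to these
# (sample SD = SE * sqrt(n)).
ARM_COST_MOMENTS = {
    "mastectomy": (87_670.0, 3_421.64, 96),
    "lumpectomy_no_rt": (27_655.0, 424.02, 240),
    "lumpectomy_rt": (50_352.0, 638.59, 389),
}


# ---------------------------------------------------------------------------
# life table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LifeTable:
    """Annual background-mortality schedule: age -> P(death within the year).

    Ages must be contiguous single years; lookups outside the covered range
    clamp to the nearest covered age (relevant when the PSA samples extreme
    entry ages).
    """

    ages: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q", q)
        if ages.ndim != 1 or ages.size == 0 or ages.shape != q.shape:
            raise ValidationError("life table needs matching 1-D age and q arrays")
        steps = np.diff(ages)
        if np.any(steps != 1):
            gap_age = int(ages[np.argmax(steps != 1)])
            raise ValidationError(
                f"life-table ages must be contiguous single years; gap after "
                f"age {gap_age}"
            )
        bad = (q < 0) | (q > 1) | ~np.isfinite(q)
        if np.any(bad):
            age = int(ages[np.argmax(bad)])
            raise ValidationError(
                f"life-table q outside [0, 1] at age {age} (q = {q[bad][0]!r})"
            )

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def q_at(self, age: float) -> float:
        """Annual death probability at integer ``age`` (clamped to coverage)."""
        idx = int(np.clip(int(age), self.min_age, self.max_age)) - self.min_age
        return float(self.q[idx])

    def covers(self, age_lo: int, age_hi: int) -> bool:
        return self.min_age <= age_lo and age_hi <= self.max_age

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "q": self.q})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def generate_lifetable(
    makeham_a: float = 5e-4,
    gompertz_b: float = 4.42e-6,
    gompertz_c: float = 1.122,
    age_range: tuple[int, int] = (0, 110),
    seed: int | None = None,
) -> LifeTable:
    """Deterministic Gompertz–Makeham life table.

    The annual death probability at integer age x is
    ``q(x) = 1 - exp(-(a + b * c**x))``: a constant background hazard ``a``
    plus a hazard growing geometrically with age.  The defaults give
    q(58) ~ 0.004 and q(85) ~ 0.08, the order of magnitude of Swedish female
    all-cause mortality.  ``seed`` is accepted for interface symmetry with
    the other generators; no sampling is involved.
    """
    if gompertz_c <= 0:
        raise ParameterError(f"gompertz_c must be positive, got {gompertz_c}")
    lo, hi = age_range
    if hi < lo:
        raise ParameterError(f"empty age_range {age_range}")
    ages = np.arange(lo, hi + 1)
    hazard = makeham_a + gompertz_b * gompertz_c ** ages.astype(float)
    if np.any(hazard < 0) or not np.all(np.isfinite(hazard)):
        raise ParameterError(
            "Gompertz-Makeham parameters produce a negative or non-finite "
            "hazard on the requested age range"
        )
    return LifeTable(ages=ages, q=1.0 - np.exp(-hazard))


def read_lifetable(path: str | Path) -> LifeTable:
    """Read a life table from CSV with header columns ``age`` and ``q``.

    Use this to supply a real national table (e.g. the WHO Swedish schedule)
    in place of the synthetic default.  Validation errors name the offending
    row.
    """
    frame = pd.read_csv(path)
    missing = {"age", "q"} - set(frame.columns)
    if missing:
        raise ValidationError(
            f"life-table CSV {path} lacks column(s) {sorted(missing)}"
        )
    return LifeTable(
        ages=frame["age"].to_numpy(dtype=int),
        q=frame["q"].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# patient-level cost registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegistryRecord:
    """One patient of the cost extract.

    ``surgery`` is the registry-level category — ``mastectomy`` or
    ``lumpectomy`` — because the source registry does not record whether a
    lumpectomy was followed by irradiation; that split is inferred downstream
    from the DRG reference cost.  ``total_cost`` is surgery plus
    hospitalisation in SEK.
    """

    patient_id: str
    surgery: str
    total_cost: float

    def __post_init__(self) -> None:
        if self.surgery not in ("mastectomy", "lumpectomy"):
            raise ValidationError(
                f"surgery must be 'mastectomy' or 'lumpectomy', got "
                f"{self.surgery!r}"
            )
        if self.total_cost < 0:
            raise ValidationError(
                f"total_cost {self.total_cost} negative for {self.patient_id}"
            )


def _gamma_shape_scale(mean: float, sd: float) -> tuple[float, float]:
    shape = (mean / sd) ** 2
    return shape, mean / shape


def generate_registry(
    n_mastectomy: int = REGISTRY_N_MASTECTOMY,
    n_lumpectomy: int = REGISTRY_N_LUMPECTOMY,
    cost_distributions: dict[str, tuple[float, float]] | None = None,
    frac_lump_with_rt: float = REGISTRY_FRAC_LUMP_RT,
    seed: int = 0,
) -> list[RegistryRecord]:
    """Simulate the in situ surgery cost registry.

    Per-patient costs are gamma distributed (right-skewed, positive).
    Lumpectomy costs are a two-component mixture — a without-irradiation
    component centred at 27,655 SEK and a with-irradiation component centred
    at 50,352 SEK, mixed at the published 389/629 proportion — so that the
    downstream DRG-threshold split approximately recovers the published
    240/389 partition.  The emitted ``surgery`` labels only distinguish
    mastectomy from lumpectomy, mirroring the source registry.

    ``cost_distributions`` maps arm name (``mastectomy``,
    ``lumpectomy_no_rt``, ``lumpectomy_rt``) to (mean, sample SD); defaults
    are moment-matched to the published means and standard errors.
    Bit-reproducible for a fixed ``seed``.
    """
    if n_mastectomy <= 0 or n_lumpectomy <= 0:
        raise ParameterError(
            f"arm counts must be positive (got {n_mastectomy} mastectomy, "
            f"{n_lumpectomy} lumpectomy)"
        )
    if not 0.0 <= frac_lump_with_rt <= 1.0:
        raise ParameterError(
            f"frac_lump_with_rt = {frac_lump_with_rt} outside [0, 1]"
        )
    if cost_distributions is None:
        cost_distributions = {
            arm: (mean, se * math.sqrt(n))
            for arm, (mean, se, n) in ARM_COST_MOMENTS.items()
        }
    rng = np.random.default_rng(seed)
    records: list[RegistryRecord] = []

    shape, scale = _gamma_shape_scale(*cost_distributions["mastectomy"])
    for cost in rng.gamma(shape, scale, size=n_mastectomy):
        records.append(
            RegistryRecord(f"P{len(records):04d}", "mastectomy", float(cost))
        )
    with_rt = rng.random(n_lumpectomy) < frac_lump_with_rt
    shapes = {
        arm: _gamma_shape_scale(*cost_distributions[arm])
        for arm in ("lumpectomy_no_rt", "lumpectomy_rt")
    }
    for is_rt in with_rt:
        shape, scale = shapes["lumpectomy_rt" if is_rt else "lumpectomy_no_rt"]
        cost = float(rng.gamma(shape, scale))
        records.append(RegistryRecord(f"P{len(records):04d}", "lumpectomy", cost))
    return records


def write_registry(records: Sequence[RegistryRecord], path: str | Path) -> None:
    """Write records as CSV (``patient_id,surgery,total_cost``)."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["patient_id", "surgery", "total_cost"])
        for rec in records:
            writer.writerow([rec.patient_id, rec.surgery, repr(rec.total_cost)])


def read_registry(path: str | Path) -> list[RegistryRecord]:
    """Read a registry extract from CSV (header as in :func:`write_registry`)."""
    frame = pd.read_csv(path)
    missing = {"patient_id", "surgery", "total_cost"} - set(frame.columns)
    if missing:
        raise ValidationError(
            f"registry CSV {path} lacks column(s) {sorted(missing)}"
        )
    return [
        RegistryRecord(str(row.patient_id), str(row.surgery), float(row.total_cost))
        for row in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# baseline cost estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BaselineCostEstimate:
    """Per-arm baseline cost summary derived from registry records."""

    n: dict[str, int]
    mean: dict[str, float]
    se: dict[str, float]

    @property
    def n_mastectomy(self) -> int:
        return self.n["mastectomy"]

    @property
    def n_lump_no_rt(self) -> int:
        return self.n["lumpectomy_no_rt"]

    @property
    def n_lump_rt(self) -> int:
        return self.n["lumpectomy_rt"]


def estimate_baseline_costs(
    records: Iterable[RegistryRecord],
    drg_reference: float = 36_439.0,
) -> BaselineCostEstimate:
    """Split pooled lumpectomy records on the DRG reference cost and summarise.

    The registry does not say which lumpectomies were followed by
    irradiation.  Records with ``total_cost <= drg_reference`` (the Swedish
    DRG cost of a lumpectomy without irradiation) are classified as the
    cheaper without-irradiation arm, the rest as with-irradiation.  Returns
    per-arm n, mean and standard error (SE = sample SD / sqrt(n)).
    """
    costs: dict[str, list[float]] = {
        "mastectomy": [],
        "lumpectomy_no_rt": [],
        "lumpectomy_rt": [],
    }
    for rec in records:
        if rec.surgery == "mastectomy":
            costs["mastectomy"].append(rec.total_cost)
        elif rec.total_cost <= drg_reference:
            costs["lumpectomy_no_rt"].append(rec.total_cost)
        else:
            costs["lumpectomy_rt"].append(rec.total_cost)
    empty = [arm for arm, values in costs.items() if not values]
    if empty:
        raise EstimationError(
            f"no records in arm(s) {empty}; cannot estimate baseline costs"
        )
    n = {arm: len(values) for arm, values in costs.items()}
    mean = {arm: float(np.mean(values)) for arm, values in costs.items()}
    se = {
        arm: (float(np.std(values, ddof=1)) / math.sqrt(len(values))
              if len(values) > 1 else float("nan"))
        for arm, values in costs.items()
    }
    return BaselineCostEstimate(n=n, mean=mean, se=se)


def inflate(amount: float, factor: float = INFLATION_2005_TO_2020) -> float:
    """Price-adjust ``amount`` by a CPI ``factor`` (defaults to 2005->2020)."""
    if factor <= 0:
        raise ParameterError(f"inflation factor must be positive, got {factor}")
    return amount * factor
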