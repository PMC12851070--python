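"""Stratified diagnosis rates and census projection.

For each assessment year, the diagnosis rate in a stratum (age group x
gender) is

    rate = (cohort members in the stratum)
           / (database patients continuously enrolled over the calendar
              year and the previous three calendar years, in the stratum)

and the projected prevalent count is ``rate x census population`` in the
same stratum, rounded half-up per stratum before summation.  Derived
metrics: prevalence per million population and overall / year-on-year
percent growth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import pandas as pd

from ._util import age_at, round_half_up
from .cohort_engine import CohortMember
from .data_model import ClaimsDatabase, Gender

__all__ = [
    "PROJECTION_AGE_GROUPS",
    "DEMOGRAPHIC_AGE_BANDS",
    "band_to_projection_group",
    "age_group_label",
    "StratumRate",
    "ProjectionResult",
    "ProjectionError",
    "denominator_counts",
    "compute_stratum_rates",
    "project_to_population",
    "growth_metrics",
    "per_million",
    "read_census",
    "write_census",
]

# Coarse bands used for projection; finer bands used for description.
PROJECTION_AGE_GROUPS: tuple[tuple[str, int, int | None], ...] = (
    ("3-17", 3, 17),
    ("18-44", 18, 44),
    ("45plus", 45, None),
)
DEMOGRAPHIC_AGE_BANDS: tuple[tuple[str, int, int | None], ...] = (
    ("3-17", 3, 17),
    ("18-44", 18, 44),
    ("45-64", 45, 64),
    ("65-84", 65, 84),
    ("85+", 85, None),
)

_BAND_TO_PROJECTION = {
    "3-17": "3-17",
    "18-44": "18-44",
    "45-64": "45plus",
    "65-84": "45plus",
    "85+": "45plus",
}


def band_to_projection_group(band: str) -> str:
    """Collapse a demographic band onto the coarser projection grouping."""
    return _BAND_TO_PROJECTION[band]


def age_group_label(
    age: int, bands: tuple[tuple[str, int, int | None], ...] = PROJECTION_AGE_GROUPS
) -> str | None:
    for label, lo, hi in bands:
        if age >= lo and (hi is None or age <= hi):
            return label
    return None


class ProjectionError(ValueError):
    pass


@dataclass(frozen=True)
class StratumRate:
    year: int
    age_group: str
    gender: Gender
    numerator: int
    denominator: int
    rate: float

    def __post_init__(self) -> None:
        if not (0 <= self.numerator <= self.denominator):
            raise ValueError(
                f"stratum ({self.age_group}, {self.gender.value}) in {self.year}: "
                f"numerator {self.numerator} outside [0, {self.denominator}]"
            )


@dataclass(frozen=True)
class ProjectionResult:
    year: int
    stratum_counts: dict[tuple[str, Gender], int]
    total: int
    total_unrounded: float
    census_total: int
    per_million: int


def denominator_counts(
    db: ClaimsDatabase,
    year: int,
    bands: tuple[tuple[str, int, int | None], ...] = PROJECTION_AGE_GROUPS,
    grace_days: int = 0,
    min_age: int = 3,
) -> dict[tuple[str, Gender], int]:
    """Patients enrolled over [Jan 1 (year-3), Dec 31 year], per stratum.

    Patients with unknown age or gender, or below ``min_age`` at the year
    start, fall outside every stratum.
    """
    window = (date(year - 3, 1, 1), date(year, 12, 31))
    merged = db.merged_enrollment(grace_days)
    counts: dict[tuple[str, Gender], int] = {}
    year_start = date(year, 1, 1)
    for demo in db.demographics:
        if demo.birth_date is None or demo.gender is Gender.UNKNOWN:
            continue
        age = age_at(demo.birth_date, year_start)
        if age < min_age:
            continue
        group = age_group_label(age, bands)
        if group is None:
            continue
        spans = merged.get(demo.patient_id, [])
        if any(s.covers(*window) for s in spans):
            key = (group, demo.gender)
            counts[key] = counts.get(key, 0) + 1
    return counts


def compute_stratum_rates(
    cohort: list[CohortMember],
    db: ClaimsDatabase,
    year: int,
    bands: tuple[tuple[str, int, int | None], ...] = PROJECTION_AGE_GROUPS,
    grace_days: int = 0,
) -> list[StratumRate]:
    """One diagnosis rate per (age group, gender) cell for the year.

    Cells with zero denominator are omitted with a warning (and would be a
    data problem if they held cohort members).
    """
    denom = denominator_counts(db, year, bands, grace_days)
    numer: dict[tuple[str, Gender], int] = {}
    for m in cohort:
        if m.age_at_year_start is None or m.gender is Gender.UNKNOWN:
            raise ValueError(
                f"cohort member {m.patient_id} lacks age/gender post-exclusions"
            )
        group = age_group_label(m.age_at_year_start, bands)
        key = (group, m.gender)
        numer[key] = numer.get(key, 0) + 1

    rates: list[StratumRate] = []
    for label, _, _ in bands:
        for gender in (Gender.FEMALE, Gender.MALE):
            key = (label, gender)
            n, d = numer.get(key, 0), denom.get(key, 0)
            if d == 0:
                if n > 0:
                    raise ProjectionError(
                        f"stratum ({label}, {gender.value}) in {year} has "
                        f"{n} cohort members but an empty denominator"
                    )
                warnings.warn(
                    f"stratum ({label}, {gender.value}) in {year} has zero "
                    "denominator; omitted",
                    stacklevel=2,
                )
                continue
            rates.append(StratumRate(year, label, gender, n, d, n / d))
    return rates


def project_to_population(
    rates: list[StratumRate],
    census: dict[tuple[int, str, str], int],
    year: int,
) -> ProjectionResult:
    """Extrapolate stratum rates to the census population for one year.

    ``census`` maps ``(year, age_group, gender)`` to a population count.
    Every stratum with a nonzero rate must have a census cell; per-stratum
    counts are rounded half-up before summation, and an unrounded total is
    kept alongside.
    """
    counts: dict[tuple[str, Gender], int] = {}
    unrounded = 0.0
    for r in rates:
        if r.year != year:
            raise ProjectionError(f"rate for {r.year} passed to projection for {year}")
        key = (year, r.age_group, r.gender.value)
        if key not in census:
            if r.rate > 0:
                raise ProjectionError(f"census population missing for stratum {key}")
            continue
        pop = census[key]
        counts[(r.age_group, r.gender)] = round_half_up(r.rate * pop)
        unrounded += r.rate * pop
    census_total = sum(
        pop for (y, _, _), pop in census.items() if y == year
    )
    total = sum(counts.values())
    return ProjectionResult(
        year=year,
        stratum_counts=counts,
        total=total,
        total_unrounded=unrounded,
        census_total=census_total,
        per_million=per_million(total, census_total) if census_total else 0,
    )


def per_million(total: float, population: float) -> int:
    """Prevalent cases per million population, rounded to an integer."""
    if population <= 0:
        raise ValueError("population must be positive")
    return round_half_up(1e6 * total / population)


@dataclass(frozen=True)
class GrowthMetrics:
    overall_pct: float | None  # first -> last, one decimal
    year_on_year_pct: dict[int, float]  # year -> % change vs previous year

    @property
    def overall_pct_int(self) -> int | None:
        return None if self.overall_pct is None else round_half_up(self.overall_pct)


def growth_metrics(totals_by_year: dict[int, float]) -> GrowthMetrics:
    """Overall and year-on-year percent changes of projected totals.

    Percent change is ``100 x (later - earlier) / earlier`` reported at one
    decimal; a zero earlier total makes the change undefined (absent).
    """
    years = sorted(totals_by_year)
    if len(years) < 2:
        raise ValueError("growth metrics need at least two years")
    first, last = totals_by_year[years[0]], totals_by_year[years[-1]]
    overall = round(100.0 * (last - first) / first, 1) if first else None
    yoy: dict[int, float] = {}
    for prev, cur in zip(years, years[1:]):
        if totals_by_year[prev]:
            yoy[cur] = round(
                100.0 * (totals_by_year[cur] - totals_by_year[prev]) / totals_by_year[prev],
                1,
            )
    return GrowthMetrics(overall, yoy)


def read_census(path: str | Path) -> dict[tuple[int, str, str], int]:
    """Census table: delimited columns year, age_group, gender, population."""
    df = pd.read_csv(path, dtype={"year": int, "population": int})
    required = {"year", "age_group", "gender", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ProjectionError(f"census file missing column(s) {sorted(missing)}")
    return {
        (int(r.year), str(r.age_group), str(r.gender)): int(r.population)
        for r in df.itertuples(index=False)
    }


def write_census(census: dict[tuple[int, str, str], int], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"year": y, "age_group": g, "gender": s, "population": p}
            for (y, g, s), p in sorted(census.items())
        ]
    ).to_csv(path, index=False)
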