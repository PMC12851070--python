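"""Rule-based identification of SBS-IF patients in a claims database.

A patient enters the annual cohort when they satisfy, for the assessment
year, the full temporal rule set:

1. *Nutrition requirement* — at least ``min_initial_nutrition_claims``
   distinct-day claims for parenteral nutrition (PN) or IV hydration since
   the lookback start.
2. *Chronic* — nutrition claims spanning at least ``chronic_gap_days``
   (default 183, i.e. "six months apart").
3. *Continuous* — a run of at least six consecutive calendar months, each
   containing at least two nutrition claims spaced >= 5 days apart,
   evaluated inside the assessment year (or on a rolling basis).
4. *Malabsorption* — a malabsorption diagnosis strictly before the first
   observed nutrition claim (optional per definition).
5. *SBS evidence* — GI surgery, post-surgical complication, or congenital
   intestinal abnormality/necrosis strictly before the first nutrition
   claim.

The index date is the first nutrition claim after the earliest SBS
evidence; inclusion further requires continuous enrollment over the index
year plus two subsequent years and over a global study window, plus known
gender and age >= 3 at the start of the assessment year.  Alternative,
less stringent definitions (used as sensitivity analyses) relax the
malabsorption rule and/or restrict nutrition to PN only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date
from enum import Enum

from ._util import age_at, month_index
from .data_model import (
    ClaimRecord,
    ClaimsDatabase,
    CodeSetRegistry,
    EnrollmentSpan,
    Gender,
    classify_claim,
)

__all__ = [
    "PN",
    "IV_HYDRATION",
    "EN",
    "MALABSORPTION_DX",
    "GI_SURGERY",
    "POST_SURGICAL_COMPLICATION",
    "CONGENITAL_ABNORMALITY",
    "EVIDENCE_CATEGORIES",
    "ContinuousWindow",
    "CohortDefinition",
    "CohortMember",
    "DispositionWaterfall",
    "primary_definition",
    "alternative_1",
    "alternative_2",
    "get_definition",
    "DEFINITION_NAMES",
    "check_nutrition_requirement",
    "check_chronic",
    "check_continuous",
    "check_malabsorption_prior",
    "check_sbs_evidence",
    "assign_index_date",
    "check_enrollment",
    "thin_dates",
    "build_cohort",
    "build_annual_cohorts",
    "RULE_SEQUENCE",
]

# Canonical rule-category keys in the code-set registry.
PN = "PN"
IV_HYDRATION = "IV_HYDRATION"
EN = "EN"
MALABSORPTION_DX = "MALABSORPTION_DX"
GI_SURGERY = "GI_SURGERY"
POST_SURGICAL_COMPLICATION = "POST_SURGICAL_COMPLICATION"
CONGENITAL_ABNORMALITY = "CONGENITAL_ABNORMALITY"

EVIDENCE_CATEGORIES = frozenset(
    {GI_SURGERY, POST_SURGICAL_COMPLICATION, CONGENITAL_ABNORMALITY}
)


class ContinuousWindow(str, Enum):
    CALENDAR_YEAR = "calendar_year"
    ROLLING_6_MONTHS = "rolling_6_months"


@dataclass(frozen=True)
class CohortDefinition:
    """Parameter bundle for one rule set (primary, alternative, or custom)."""

    name: str
    nutrition_categories: frozenset[str] = frozenset({PN, IV_HYDRATION})
    min_initial_nutrition_claims: int = 1
    require_chronic: bool = True
    chronic_gap_days: int = 183
    require_continuous: bool = True
    continuous_min_claims_per_month: int = 2
    continuous_min_spacing_days: int = 5
    continuous_min_months: int = 6
    continuous_window: ContinuousWindow = ContinuousWindow.CALENDAR_YEAR
    require_malabsorption: bool = True
    require_sbs_evidence: bool = True
    enrollment_years_after_index: int = 2
    min_age_years: int = 3
    lookback_start: date = date(2016, 1, 1)
    global_window: tuple[date, date] = (date(2018, 1, 1), date(2021, 12, 31))
    allow_same_day_before: bool = False

    def with_options(self, **kwargs) -> "CohortDefinition":
        return replace(self, **kwargs)


def primary_definition() -> CohortDefinition:
    return CohortDefinition(name="primary")


def alternative_1() -> CohortDefinition:
    """PN required; malabsorption diagnosis not required."""
    return CohortDefinition(
        name="alternative_1",
        nutrition_categories=frozenset({PN}),
        require_malabsorption=False,
    )


def alternative_2() -> CohortDefinition:
    """PN or IV hydration; malabsorption diagnosis not required."""
    return CohortDefinition(name="alternative_2", require_malabsorption=False)


DEFINITION_NAMES = ("primary", "alternative_1", "alternative_2")


def get_definition(name: str) -> CohortDefinition:
    factories = {
        "primary": primary_definition,
        "alternative_1": alternative_1,
        "alternative_2": alternative_2,
    }
    try:
        return factories[name]()
    except KeyError:
        raise KeyError(
            f"unknown definition {name!r}; expected one of {DEFINITION_NAMES}"
        ) from None


@dataclass(frozen=True)
class CohortMember:
    patient_id: str
    index_date: date
    qualifying_years: frozenset[int]
    definition_name: str
    age_at_index: int
    age_at_year_start: int
    gender: Gender


@dataclass
class DispositionWaterfall:
    """Ordered survivor counts after each successive inclusion rule."""

    steps: list[tuple[str, int]] = field(default_factory=list)

    def append(self, label: str, remaining: int) -> None:
        if self.steps and remaining > self.steps[-1][1]:
            raise ValueError("waterfall counts must be non-increasing")
        self.steps.append((label, remaining))

    def to_records(self) -> list[dict]:
        return [{"rule": label, "patients_remaining": n} for label, n in self.steps]


# ---------------------------------------------------------------------------
# Individual rule checks
# ---------------------------------------------------------------------------


def nutrition_claim_dates(
    claims: list[ClaimRecord],
    registry: CodeSetRegistry,
    definition: CohortDefinition,
) -> list[date]:
    """Sorted distinct service dates of nutrition claims since lookback."""
    dates = {
        c.service_date
        for c in claims
        if c.service_date >= definition.lookback_start
        and classify_claim(c, registry) & definition.nutrition_categories
    }
    return sorted(dates)


def check_nutrition_requirement(
    claims: list[ClaimRecord],
    registry: CodeSetRegistry,
    definition: CohortDefinition,
) -> tuple[bool, date | None]:
    """Nutrition requirement; returns the first parenteral-support date."""
    dates = nutrition_claim_dates(claims, registry, definition)
    passed = len(dates) >= definition.min_initial_nutrition_claims
    return passed, (dates[0] if dates else None)


def check_chronic(dates: list[date], chronic_gap_days: int = 183) -> bool:
    """Two nutrition claims at least ``chronic_gap_days`` apart."""
    if len(dates) < 2:
        return False
    return (max(dates) - min(dates)).days >= chronic_gap_days


def thin_dates(dates: list[date], min_spacing_days: int) -> list[date]:
    """Greedy earliest-first subset of sorted dates pairwise >= spacing apart.

    Greedy selection on sorted dates yields a maximum-size subset for this
    constraint, so patients get the benefit of the doubt; same-day
    duplicates collapse because inputs are distinct dates.
    """
    kept: list[date] = []
    for d in dates:
        if not kept or (d - kept[-1]).days >= min_spacing_days:
            kept.append(d)
    return kept


def _month_claim_counts(dates: list[date], definition: CohortDefinition) -> dict[int, int]:
    by_month: dict[int, list[date]] = {}
    for d in dates:
        by_month.setdefault(month_index(d), []).append(d)
    return {
        m: len(thin_dates(sorted(ds), definition.continuous_min_spacing_days))
        for m, ds in by_month.items()
    }


def check_continuous(
    dates: list[date], year: int, definition: CohortDefinition
) -> bool:
    """Continuous-nutrition rule for one assessment year.

    CALENDAR_YEAR mode: a run of >= ``continuous_min_months`` consecutive
    calendar months *within the year*, each with >=
    ``continuous_min_claims_per_month`` nutrition claims spaced >=
    ``continuous_min_spacing_days`` apart.  ROLLING_6_MONTHS mode lets the
    run straddle year boundaries provided it intersects the year.
    """
    counts = _month_claim_counts(dates, definition)
    need = definition.continuous_min_claims_per_month
    run_len = definition.continuous_min_months
    qualifying = {m for m, n in counts.items() if n >= need}
    if definition.continuous_window is ContinuousWindow.CALENDAR_YEAR:
        months = [month_index(date(year, m, 1)) for m in range(1, 13)]
        starts = range(0, 13 - run_len)
        return any(
            all(months[s + k] in qualifying for k in range(run_len)) for s in starts
        )
    first = month_index(date(year, 1, 1))
    last = month_index(date(year, 12, 1))
    # run of run_len months intersecting [first, last]
    for start in range(first - run_len + 1, last + 1):
        if all((start + k) in qualifying for k in range(run_len)):
            return True
    return False


def _before(claim_date: date, cutoff: date, allow_same_day: bool) -> bool:
    return claim_date <= cutoff if allow_same_day else claim_date < cutoff


def check_malabsorption_prior(
    claims: list[ClaimRecord],
    registry: CodeSetRegistry,
    first_ps_date: date,
    allow_same_day: bool = False,
) -> bool:
    """Malabsorption diagnosis before the first parenteral-support claim."""
    return any(
        MALABSORPTION_DX in classify_claim(c, registry)
        and _before(c.service_date, first_ps_date, allow_same_day)
        for c in claims
    )


def check_sbs_evidence(
    claims: list[ClaimRecord],
    registry: CodeSetRegistry,
    first_ps_date: date,
    allow_same_day: bool = False,
) -> tuple[bool, date | None]:
    """Surgical/congenital SBS evidence before the first nutrition claim.

    Returns the earliest matching evidence date (over all three arms).
    """
    evidence_dates = [
        c.service_date
        for c in claims
        if classify_claim(c, registry) & EVIDENCE_CATEGORIES
        and _before(c.service_date, first_ps_date, allow_same_day)
    ]
    if not evidence_dates:
        return False, None
    return True, min(evidence_dates)


def assign_index_date(
    claims: list[ClaimRecord],
    registry: CodeSetRegistry,
    definition: CohortDefinition,
) -> date | None:
    """First nutrition claim strictly after the earliest SBS evidence.

    Falls back to the first nutrition claim when evidence is not required
    and none exists.  Returns None (an ineligibility signal, not an error)
    when no nutrition claim follows the evidence.
    """
    nut_dates = nutrition_claim_dates(claims, registry, definition)
    if not nut_dates:
        return None
    all_evidence = [
        c.service_date
        for c in claims
        if classify_claim(c, registry) & EVIDENCE_CATEGORIES
    ]
    if not all_evidence:
        return nut_dates[0] if not definition.require_sbs_evidence else None
    earliest_evidence = min(all_evidence)
    after = [
        d
        for d in nut_dates
        if (d >= earliest_evidence if definition.allow_same_day_before else d > earliest_evidence)
    ]
    return after[0] if after else None


def check_enrollment(
    spans: list[EnrollmentSpan],
    index_date: date,
    definition: CohortDefinition,
) -> bool:
    """Continuous coverage over the index window and the global window.

    The index window is Jan 1 of the index year through Dec 31 of the index
    year plus ``enrollment_years_after_index``; each required window must be
    covered by a single normalized span.
    """
    windows = [
        (
            date(index_date.year, 1, 1),
            date(index_date.year + definition.enrollment_years_after_index, 12, 31),
        ),
        definition.global_window,
    ]
    return all(
        any(span.covers(start, end) for span in spans) for start, end in windows
    )


# ---------------------------------------------------------------------------
# Whole-patient evaluation and cohort construction
# ---------------------------------------------------------------------------

RULE_SEQUENCE = (
    "nutrition",
    "chronic",
    "continuous",
    "malabsorption",
    "sbs_evidence",
    "index_enrollment",
    "age_gender",
)


@dataclass
class PatientEvaluation:
    patient_id: str
    rules: dict[str, bool]
    first_ps_date: date | None = None
    index_date: date | None = None
    age_at_year_start: int | None = None
    age_at_index: int | None = None
    gender: Gender = Gender.UNKNOWN

    @property
    def eligible(self) -> bool:
        return all(self.rules.values())


def evaluate_patient(
    patient_id: str,
    db: ClaimsDatabase,
    registry: CodeSetRegistry,
    definition: CohortDefinition,
    year: int,
    merged_spans: dict[str, list[EnrollmentSpan]],
) -> PatientEvaluation:
    """Evaluate every active inclusion rule for one patient and year.

    All rules are evaluated independently (membership is their conjunction),
    so the filter order affects only the disposition waterfall.
    """
    claims = db.claims_for(patient_id)
    demo = db.demographics_for(patient_id)
    rules: dict[str, bool] = {}

    nut_pass, first_ps = check_nutrition_requirement(claims, registry, definition)
    rules["nutrition"] = nut_pass
    nut_dates = nutrition_claim_dates(claims, registry, definition)

    if definition.require_chronic:
        rules["chronic"] = check_chronic(nut_dates, definition.chronic_gap_days)
    if definition.require_continuous:
        rules["continuous"] = check_continuous(nut_dates, year, definition)
    if definition.require_malabsorption:
        rules["malabsorption"] = first_ps is not None and check_malabsorption_prior(
            claims, registry, first_ps, definition.allow_same_day_before
        )
    if definition.require_sbs_evidence:
        evid_pass, _ = (
            check_sbs_evidence(
                claims, registry, first_ps, definition.allow_same_day_before
            )
            if first_ps is not None
            else (False, None)
        )
        rules["sbs_evidence"] = evid_pass

    index_date = assign_index_date(claims, registry, definition)
    spans = merged_spans.get(patient_id, [])
    rules["index_enrollment"] = index_date is not None and check_enrollment(
        spans, index_date, definition
    )

    year_start = date(year, 1, 1)
    age_known = demo.birth_date is not None
    gender_known = demo.gender is not Gender.UNKNOWN
    age_ys = age_at(demo.birth_date, year_start) if age_known else None
    rules["age_gender"] = (
        age_known and gender_known and age_ys >= definition.min_age_years
    )

    return PatientEvaluation(
        patient_id=patient_id,
        rules=rules,
        first_ps_date=first_ps,
        index_date=index_date,
        age_at_year_start=age_ys,
        age_at_index=(
            age_at(demo.birth_date, index_date)
            if age_known and index_date is not None
            else None
        ),
        gender=demo.gender,
    )


def build_cohort(
    db: ClaimsDatabase,
    registry: CodeSetRegistry,
    definition: CohortDefinition,
    year: int,
    grace_days: int = 0,
    rule_order: tuple[str, ...] | None = None,
) -> tuple[list[CohortMember], DispositionWaterfall]:
    """Apply the definition's rules for one assessment year.

    Returns the cohort members (sorted by patient id) and the disposition
    waterfall of survivor counts.  ``rule_order`` may permute the active
    rules; it changes the waterfall but never the member set.
    """
    active = [
        r
        for r in RULE_SEQUENCE
        if not (
            (r == "chronic" and not definition.require_chronic)
            or (r == "continuous" and not definition.require_continuous)
            or (r == "malabsorption" and not definition.require_malabsorption)
            or (r == "sbs_evidence" and not definition.require_sbs_evidence)
        )
    ]
    if rule_order is not None:
        if sorted(rule_order) != sorted(active):
            raise ValueError(
                f"rule_order must be a permutation of the active rules {active}"
            )
        active = list(rule_order)

    merged = db.merged_enrollment(grace_days)
    evaluations = {
        pid: evaluate_patient(pid, db, registry, definition, year, merged)
        for pid in db.patients()
    }

    waterfall = DispositionWaterfall()
    remaining = list(evaluations)
    waterfall.append("candidates", len(remaining))
    for rule in active:
        remaining = [pid for pid in remaining if evaluations[pid].rules[rule]]
        waterfall.append(rule, len(remaining))

    members = [
        CohortMember(
            patient_id=pid,
            index_date=evaluations[pid].index_date,
            qualifying_years=frozenset({year}),
            definition_name=definition.name,
            age_at_index=evaluations[pid].age_at_index,
            age_at_year_start=evaluations[pid].age_at_year_start,
            gender=evaluations[pid].gender,
        )
        for pid in sorted(remaining)
    ]
    return members, waterfall


def build_annual_cohorts(
    db: ClaimsDatabase,
    registry: CodeSetRegistry,
    definition: CohortDefinition,
    years: list[int],
    grace_days: int = 0,
) -> dict[int, tuple[list[CohortMember], DispositionWaterfall]]:
    """Build one cohort per assessment year (annual point prevalence)."""
    return {
        year: build_cohort(db, registry, definition, year, grace_days)
        for year in years
    }


def qualifying_years_map(
    annual: dict[int, tuple[list[CohortMember], DispositionWaterfall]],
) -> dict[str, set[int]]:
    """patient_id -> set of years in which the patient qualified."""
    out: dict[str, set[int]] = {}
    for year, (members, _) in annual.items():
        for m in members:
            out.setdefault(m.patient_id, set()).add(year)
    return out
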