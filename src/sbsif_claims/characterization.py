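"""Descriptive tables for an annual cohort.

Demographics (age bands, gender), nutrition-code combinations (presence of
parenteral nutrition, IV hydration, and enteral nutrition claims),
configurable grouped comorbidity/infection tabulations, and medication
classes.  All counts are per-patient presence (repeat claims count once)
and percentages are integer half-up of count / cohort size.

Characteristics default to the member's entire visible claim history; an
optional symmetric window (in days) around the index date restricts the
assessed claims.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from datetime import timedelta
from pathlib import Path

import pandas as pd

from ._util import percent
from .cohort_engine import EN, IV_HYDRATION, PN, CohortMember
from .data_model import (
    ClaimCategory,
    ClaimRecord,
    ClaimsDatabase,
    CodeSetRegistry,
    Gender,
    classify_claim,
)
from .projection import DEMOGRAPHIC_AGE_BANDS, age_group_label

__all__ = [
    "CharacterizationTable",
    "demographics_table",
    "nutrition_combination_table",
    "grouped_condition_table",
    "medication_class_table",
]


@dataclass
class CharacterizationTable:
    """Ordered (label, count, percent) rows over a cohort."""

    table_name: str
    rows: list[tuple[str, int, int]]
    cohort_size: int
    overlapping_rows: bool = False  # rows may overlap, columns can sum > 100%

    def __post_init__(self) -> None:
        for label, count, pct in self.rows:
            if not (0 <= count <= self.cohort_size):
                raise ValueError(
                    f"{self.table_name}: row {label!r} count {count} outside "
                    f"[0, {self.cohort_size}]"
                )
            if self.cohort_size and pct != percent(count, self.cohort_size):
                raise ValueError(
                    f"{self.table_name}: row {label!r} percent inconsistent"
                )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["label", "count", "percent"])

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def __str__(self) -> str:
        header = f"{self.table_name} (cohort n={self.cohort_size})"
        note = (
            "\nnote: rows may overlap; percentages can sum to more than 100"
            if self.overlapping_rows
            else ""
        )
        return header + "\n" + self.to_dataframe().to_string(index=False) + note


def _row(label: str, count: int, size: int) -> tuple[str, int, int]:
    return (label, count, percent(count, size) if size else 0)


def _member_claims(
    db: ClaimsDatabase, member: CohortMember, window_days: int | None
) -> list[ClaimRecord]:
    claims = db.claims_for(member.patient_id)
    if window_days is None:
        return claims
    lo = member.index_date - timedelta(days=window_days)
    hi = member.index_date + timedelta(days=window_days)
    return [c for c in claims if lo <= c.service_date <= hi]


def demographics_table(cohort: list[CohortMember]) -> CharacterizationTable:
    """Age-band and gender rows; each group partitions the cohort exactly."""
    size = len(cohort)
    rows: list[tuple[str, int, int]] = []
    for label, _, _ in DEMOGRAPHIC_AGE_BANDS:
        n = sum(
            1
            for m in cohort
            if age_group_label(m.age_at_year_start, DEMOGRAPHIC_AGE_BANDS) == label
        )
        rows.append(_row(f"Age {label}", n, size))
    for gender, label in ((Gender.FEMALE, "Female"), (Gender.MALE, "Male")):
        n = sum(1 for m in cohort if m.gender is gender)
        rows.append(_row(label, n, size))
    return CharacterizationTable("demographics", rows, size)


_NUTRITION_ROWS = (
    "At least one EN claim",
    "At least one IV hydration claim",
    "Only PN claims",
    "PN and IV hydration claims",
    "PN and EN claims",
    "PN, EN, and IV hydration claims",
)


def nutrition_combination_table(
    cohort: list[CohortMember],
    db: ClaimsDatabase,
    registry: CodeSetRegistry,
    window_days: int | None = None,
) -> CharacterizationTable:
    """Nutrition-code combinations per member.

    The two "at least one" rows deliberately overlap the exclusive
    PN-combination rows, so column percentages can exceed 100.
    """
    size = len(cohort)
    counts = dict.fromkeys(_NUTRITION_ROWS, 0)
    for m in cohort:
        cats = set()
        for c in _member_claims(db, m, window_days):
            cats |= classify_claim(c, registry)
        pn, iv, en = PN in cats, IV_HYDRATION in cats, EN in cats
        if en:
            counts["At least one EN claim"] += 1
        if iv:
            counts["At least one IV hydration claim"] += 1
        if pn and not iv and not en:
            counts["Only PN claims"] += 1
        elif pn and iv and not en:
            counts["PN and IV hydration claims"] += 1
        elif pn and en and not iv:
            counts["PN and EN claims"] += 1
        elif pn and en and iv:
            counts["PN, EN, and IV hydration claims"] += 1
    rows = [_row(label, counts[label], size) for label in _NUTRITION_ROWS]
    return CharacterizationTable(
        "nutrition_combinations", rows, size, overlapping_rows=True
    )


def _as_registry(
    grouping: CodeSetRegistry | Mapping[str, list[str]],
) -> CodeSetRegistry:
    if isinstance(grouping, CodeSetRegistry):
        return grouping
    return CodeSetRegistry.from_dict(grouping)


def _presence_table(
    name: str,
    cohort: list[CohortMember],
    db: ClaimsDatabase,
    grouping: CodeSetRegistry,
    keys: list[str],
    window_days: int | None,
    category_filter: ClaimCategory | None = None,
) -> CharacterizationTable:
    size = len(cohort)
    counts = dict.fromkeys(keys, 0)
    for m in cohort:
        seen: set[str] = set()
        for c in _member_claims(db, m, window_days):
            if category_filter is not None and c.claim_category is not category_filter:
                continue
            seen |= classify_claim(c, grouping) & counts.keys()
        for key in seen:
            counts[key] += 1
    rows = [_row(key, counts[key], size) for key in keys]
    return CharacterizationTable(name, rows, size, overlapping_rows=True)


def grouped_condition_table(
    cohort: list[CohortMember],
    db: ClaimsDatabase,
    grouping_map: CodeSetRegistry | Mapping[str, list[str]],
    window_days: int | None = None,
    row_order: list[str] | None = None,
) -> CharacterizationTable:
    """Per-patient presence of each diagnosis grouping (e.g. CCSR-style).

    Any diagnosis-to-group map is accepted; a member counts toward a group
    once, however many matching claims they have.
    """
    grouping = _as_registry(grouping_map)
    keys = row_order if row_order is not None else sorted(grouping.keys())
    return _presence_table(
        "grouped_conditions", cohort, db, grouping, keys, window_days
    )


def medication_class_table(
    cohort: list[CohortMember],
    db: ClaimsDatabase,
    class_map: CodeSetRegistry | Mapping[str, list[str]],
    window_days: int | None = None,
    row_order: list[str] | None = None,
) -> CharacterizationTable:
    """Per-patient presence of medication classes among pharmacy claims only."""
    classes = _as_registry(class_map)
    keys = row_order if row_order is not None else sorted(classes.keys())
    return _presence_table(
        "medication_classes", cohort, db, classes, keys, window_days,
        category_filter=ClaimCategory.PHARMACY,
    )
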