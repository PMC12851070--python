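"""Claims-world data types and delimited-file I/O.

Everything downstream (cohort rules, projection, characterization) consumes
only the types defined here: individual claim lines, continuous-coverage
enrollment spans, patient demographics, and a registry mapping rule
categories (parenteral nutrition, IV hydration, malabsorption diagnoses,
GI surgery, ...) onto concrete ``(code_system, code)`` pairs.  The registry
is deliberately user-supplied configuration: no clinical code list is baked
into the package.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from datetime import date, timedelta
from enum import Enum
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "CodeSystem",
    "ClaimCategory",
    "PayerChannel",
    "Gender",
    "ClaimRecord",
    "EnrollmentSpan",
    "PatientDemographics",
    "CodeSetRegistry",
    "ClaimsDatabase",
    "ClaimsInputError",
    "ClaimsSchemaError",
    "ClaimsValidationError",
    "classify_claim",
    "merge_enrollment",
    "read_claims_database",
    "write_claims_database",
]


class CodeSystem(str, Enum):
    ICD10_DX = "ICD10-DX"
    ICD10_PCS = "ICD10-PCS"
    CPT = "CPT"
    HCPCS = "HCPCS"
    NDC = "NDC"
    OTHER = "OTHER"


class ClaimCategory(str, Enum):
    MEDICAL = "MEDICAL"
    PHARMACY = "PHARMACY"


class PayerChannel(str, Enum):
    COMMERCIAL = "COMMERCIAL"
    MEDICARE = "MEDICARE"
    MEDICAID = "MEDICAID"
    OTHER = "OTHER"


class Gender(str, Enum):
    FEMALE = "FEMALE"
    MALE = "MALE"
    UNKNOWN = "UNKNOWN"


class ClaimsInputError(FileNotFoundError):
    """A required input file is missing."""


class ClaimsSchemaError(ValueError):
    """A mandatory column is absent from an input table."""


class ClaimsValidationError(ValueError):
    """One or more rows failed validation; carries per-row messages."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        preview = "; ".join(self.errors[:5])
        more = "" if len(self.errors) <= 5 else f" (+{len(self.errors) - 5} more)"
        super().__init__(f"{len(self.errors)} validation error(s): {preview}{more}")


@dataclass(frozen=True, slots=True)
class ClaimRecord:
    """One adjudicated medical or pharmacy claim line."""

    patient_id: str
    service_date: date
    code: str
    code_system: CodeSystem
    claim_category: ClaimCategory = ClaimCategory.MEDICAL
    payer_channel: PayerChannel = PayerChannel.COMMERCIAL

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not self.code:
            raise ValueError("code must be non-empty")
        if not isinstance(self.service_date, date):
            raise TypeError("service_date must be a datetime.date")


@dataclass(frozen=True, slots=True)
class EnrollmentSpan:
    """A closed interval of continuous medical+pharmacy coverage."""

    patient_id: str
    start_date: date
    end_date: date

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.end_date < self.start_date:
            raise ValueError(
                f"end_date {self.end_date} precedes start_date {self.start_date}"
            )

    def covers(self, start: date, end: date) -> bool:
        return self.start_date <= start and self.end_date >= end


@dataclass(frozen=True, slots=True)
class PatientDemographics:
    patient_id: str
    birth_date: date | None
    gender: Gender
    race: str | None = None


class CodeSetRegistry:
    """Named map from rule-category keys to sets of (code_system, code) pairs.

    A pair may belong to several categories; looking up a claim returns the
    (possibly empty) frozenset of categories that contain its code.
    """

    def __init__(self, sets: Mapping[str, Iterable[tuple[CodeSystem | str, str]]]):
        self._sets: dict[str, frozenset[tuple[CodeSystem, str]]] = {}
        index: dict[tuple[CodeSystem, str], set[str]] = {}
        for key, pairs in sets.items():
            normalized = frozenset(
                (CodeSystem(system), str(code)) for system, code in pairs
            )
            if not normalized:
                raise ValueError(f"category {key!r} has an empty code set")
            self._sets[key] = normalized
            for pair in normalized:
                index.setdefault(pair, set()).add(key)
        self._index: dict[tuple[CodeSystem, str], frozenset[str]] = {
            pair: frozenset(keys) for pair, keys in index.items()
        }

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Iterable[str]]) -> "CodeSetRegistry":
        """Build from ``{category: ["HCPCS:B4185", "ICD10-DX:K90.9", ...]}``."""
        sets: dict[str, list[tuple[str, str]]] = {}
        for key, entries in mapping.items():
            pairs = []
            for entry in entries:
                system, sep, code = str(entry).partition(":")
                if not sep or not code:
                    raise ValueError(
                        f"entry {entry!r} under {key!r} is not 'SYSTEM:code'"
                    )
                pairs.append((system, code))
            sets[key] = pairs
        return cls(sets)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CodeSetRegistry":
        path = Path(path)
        if not path.exists():
            raise ClaimsInputError(f"registry file not found: {path}")
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        mapping = payload.get("code_sets", payload) if isinstance(payload, dict) else payload
        return cls.from_dict(mapping)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "code_sets": {
                key: sorted(f"{system.value}:{code}" for system, code in pairs)
                for key, pairs in sorted(self._sets.items())
            }
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    def categories_of(self, code_system: CodeSystem | str, code: str) -> frozenset[str]:
        return self._index.get((CodeSystem(code_system), code), frozenset())

    def codes(self, key: str) -> frozenset[tuple[CodeSystem, str]]:
        return self._sets[key]

    def keys(self) -> list[str]:
        return list(self._sets)

    def __contains__(self, key: str) -> bool:
        return key in self._sets

    def require(self, keys: Iterable[str]) -> None:
        missing = [k for k in keys if k not in self._sets]
        if missing:
            raise KeyError(f"registry is missing required categories: {missing}")


def classify_claim(claim: ClaimRecord, registry: CodeSetRegistry) -> frozenset[str]:
    """All rule categories whose code set contains this claim's code."""
    return registry.categories_of(claim.code_system, claim.code)


def merge_enrollment(
    spans: Iterable[EnrollmentSpan], grace_days: int = 0
) -> dict[str, list[EnrollmentSpan]]:
    """Normalize enrollment per patient.

    Overlapping spans, and adjacent spans separated by a coverage gap of at
    most ``grace_days`` whole days, are coalesced.  Output spans per patient
    are disjoint and sorted; the operation is idempotent.
    """
    if grace_days < 0:
        raise ValueError("grace_days must be >= 0")
    by_patient: dict[str, list[EnrollmentSpan]] = {}
    for span in spans:
        by_patient.setdefault(span.patient_id, []).append(span)
    merged: dict[str, list[EnrollmentSpan]] = {}
    for pid, plist in by_patient.items():
        plist.sort(key=lambda s: (s.start_date, s.end_date))
        out: list[EnrollmentSpan] = []
        for span in plist:
            if out:
                prev = out[-1]
                gap = (span.start_date - prev.end_date).days - 1
                if gap <= grace_days:
                    if span.end_date > prev.end_date:
                        out[-1] = EnrollmentSpan(pid, prev.start_date, span.end_date)
                    continue
            out.append(span)
        merged[pid] = out
    return merged


class ClaimsDatabase:
    """In-memory claims database: claims + enrollment + demographics.

    Validates referential integrity on construction (every claim's patient
    must have a demographics row) and indexes claims per patient sorted by
    service date.
    """

    def __init__(
        self,
        claims: Iterable[ClaimRecord],
        enrollment: Iterable[EnrollmentSpan],
        demographics: Iterable[PatientDemographics],
        validate: bool = True,
    ):
        self.claims: list[ClaimRecord] = list(claims)
        self.enrollment: list[EnrollmentSpan] = list(enrollment)
        self.demographics: list[PatientDemographics] = list(demographics)
        self._demo_by_id: dict[str, PatientDemographics] = {}
        for demo in self.demographics:
            if validate and demo.patient_id in self._demo_by_id:
                raise ClaimsValidationError(
                    [f"duplicate demographics row for patient {demo.patient_id!r}"]
                )
            self._demo_by_id[demo.patient_id] = demo
        if validate:
            orphans = sorted(
                {c.patient_id for c in self.claims} - self._demo_by_id.keys()
            )
            if orphans:
                raise ClaimsValidationError(
                    [f"claim references unknown patient {pid!r}" for pid in orphans]
                )
        self._claims_by_id: dict[str, list[ClaimRecord]] = {}
        for claim in self.claims:
            self._claims_by_id.setdefault(claim.patient_id, []).append(claim)
        for plist in self._claims_by_id.values():
            plist.sort(key=lambda c: (c.service_date, c.code_system.value, c.code))
        self._merged_cache: dict[int, dict[str, list[EnrollmentSpan]]] = {}

    def patients(self) -> list[str]:
        return [d.patient_id for d in self.demographics]

    def demographics_for(self, patient_id: str) -> PatientDemographics:
        return self._demo_by_id[patient_id]

    def claims_for(self, patient_id: str) -> list[ClaimRecord]:
        return self._claims_by_id.get(patient_id, [])

    def merged_enrollment(self, grace_days: int = 0) -> dict[str, list[EnrollmentSpan]]:
        if grace_days not in self._merged_cache:
            self._merged_cache[grace_days] = merge_enrollment(
                self.enrollment, grace_days
            )
        return self._merged_cache[grace_days]

    @property
    def n_patients(self) -> int:
        return len(self.demographics)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ClaimsDatabase({self.n_patients} patients, "
            f"{len(self.claims)} claims, {len(self.enrollment)} enrollment spans)"
        )


_CLAIM_COLUMNS = [
    "patient_id",
    "service_date",
    "code",
    "code_system",
    "claim_category",
    "payer_channel",
]
_ENROLLMENT_COLUMNS = ["patient_id", "start_date", "end_date"]
_DEMOGRAPHICS_COLUMNS = ["patient_id", "birth_date", "gender", "race"]


def _read_table(
    path: str | Path,
    required: list[str],
    optional: list[str],
    remap: Mapping[str, str] | None,
    delimiter: str,
) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ClaimsInputError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if remap:
        # remap is canonical -> file column name
        rename = {v: k for k, v in remap.items()}
        df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ClaimsSchemaError(f"{path.name}: missing mandatory column(s) {missing}")
    for col in optional:
        if col not in df.columns:
            df[col] = ""
    return df


def _parse_date(value: str) -> date:
    return date.fromisoformat(value.strip())


def read_claims_database(
    claims_path: str | Path,
    enrollment_path: str | Path,
    demographics_path: str | Path,
    schema_config: Mapping[str, Mapping[str, str]] | None = None,
    delimiter: str = ",",
) -> ClaimsDatabase:
    """Read the three delimited tables into a validated :class:`ClaimsDatabase`.

    ``schema_config`` optionally remaps column names per table, e.g.
    ``{"claims": {"service_date": "svc_dt"}}``.  Row-level problems
    (unparseable dates, inverted spans, bad enum tokens) are collected with
    their file row numbers and raised together as a
    :class:`ClaimsValidationError`.
    """
    schema_config = schema_config or {}
    errors: list[str] = []

    claims_df = _read_table(
        claims_path, _CLAIM_COLUMNS[:4], _CLAIM_COLUMNS[4:],
        schema_config.get("claims"), delimiter,
    )
    claims: list[ClaimRecord] = []
    for i, row in enumerate(claims_df.itertuples(index=False)):
        rowno = i + 2  # header is file row 1
        try:
            claims.append(
                ClaimRecord(
                    patient_id=row.patient_id,
                    service_date=_parse_date(row.service_date),
                    code=row.code,
                    code_system=CodeSystem(row.code_system),
                    claim_category=ClaimCategory(row.claim_category or "MEDICAL"),
                    payer_channel=PayerChannel(row.payer_channel or "OTHER"),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"claims row {rowno}: {exc}")

    enrollment_df = _read_table(
        enrollment_path, _ENROLLMENT_COLUMNS, [],
        schema_config.get("enrollment"), delimiter,
    )
    enrollment: list[EnrollmentSpan] = []
    for i, row in enumerate(enrollment_df.itertuples(index=False)):
        rowno = i + 2
        try:
            enrollment.append(
                EnrollmentSpan(
                    patient_id=row.patient_id,
                    start_date=_parse_date(row.start_date),
                    end_date=_parse_date(row.end_date),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"enrollment row {rowno}: {exc}")

    demo_df = _read_table(
        demographics_path, _DEMOGRAPHICS_COLUMNS[:3], _DEMOGRAPHICS_COLUMNS[3:],
        schema_config.get("demographics"), delimiter,
    )
    demographics: list[PatientDemographics] = []
    for i, row in enumerate(demo_df.itertuples(index=False)):
        rowno = i + 2
        try:
            birth = _parse_date(row.birth_date) if row.birth_date else None
            demographics.append(
                PatientDemographics(
                    patient_id=row.patient_id,
                    birth_date=birth,
                    gender=Gender(row.gender or "UNKNOWN"),
                    race=row.race or None,
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"demographics row {rowno}: {exc}")

    if errors:
        raise ClaimsValidationError(errors)
    return ClaimsDatabase(claims, enrollment, demographics)


def write_claims_database(
    db: ClaimsDatabase,
    claims_path: str | Path,
    enrollment_path: str | Path,
    demographics_path: str | Path,
    delimiter: str = ",",
) -> None:
    """Write the three tables back out (ISO-8601 dates, UTF-8)."""
    pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "service_date": c.service_date.isoformat(),
                "code": c.code,
                "code_system": c.code_system.value,
                "claim_category": c.claim_category.value,
                "payer_channel": c.payer_channel.value,
            }
            for c in db.claims
        ],
        columns=_CLAIM_COLUMNS,
    ).to_csv(claims_path, sep=delimiter, index=False)
    pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "start_date": s.start_date.isoformat(),
                "end_date": s.end_date.isoformat(),
            }
            for s in db.enrollment
        ],
        columns=_ENROLLMENT_COLUMNS,
    ).to_csv(enrollment_path, sep=delimiter, index=False)
    pd.DataFrame(
        [
            {
                "patient_id": d.patient_id,
                "birth_date": d.birth_date.isoformat() if d.birth_date else "",
                "gender": d.gender.value,
                "race": d.race or "",
            }
            for d in db.demographics
        ],
        columns=_DEMOGRAPHICS_COLUMNS,
    ).to_csv(demographics_path, sep=delimiter, index=False)
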