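"""Synthetic administrative-claims generator with known ground truth.

Emulates the structure of a large multi-payer claims database at desk
scale: multi-year enrollment spans, recurring home-nutrition supply claims
every 1-2 weeks, diagnosis and surgery claims with controlled temporal
ordering, and three planted patient strata —

* TRUE_CASE   — trajectories constructed to satisfy every inclusion rule
                for a chosen set of qualifying calendar years;
* NEAR_MISS   — trajectories violating exactly one named rule;
* BACKGROUND  — patients with junk claims, or "confusers" reusing real
                rule codes in non-qualifying patterns.

Because no real clinical code list ships with the package, generated
claims use a small fictitious vocabulary (``PN001``, ``HYD01``,
``MAL01``, ...) registered by :func:`default_registry`; background junk
codes are drawn from a disjoint vocabulary so they can never partially
match a rule.

Each patient draws from its own pseudo-random stream derived from
``(seed, patient ordinal)``, so adding patients never perturbs existing
ones and the same seed reproduces a byte-identical database.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_engine import (
    CONGENITAL_ABNORMALITY,
    EN,
    GI_SURGERY,
    IV_HYDRATION,
    MALABSORPTION_DX,
    PN,
    POST_SURGICAL_COMPLICATION,
)
from .data_model import (
    ClaimCategory,
    ClaimRecord,
    ClaimsDatabase,
    CodeSetRegistry,
    CodeSystem,
    EnrollmentSpan,
    Gender,
    PatientDemographics,
    PayerChannel,
    write_claims_database,
)

__all__ = [
    "AGE_BANDS",
    "RULE_KEYS",
    "Label",
    "GroundTruthLabel",
    "SyntheticConfig",
    "default_registry",
    "generate_true_case",
    "generate_near_miss",
    "generate_background",
    "generate_database",
    "repair_near_miss",
    "write_labels",
    "read_labels",
    "write_database",
]

# Demographic age bands (completed years at the reference year start).
AGE_BANDS: tuple[tuple[str, int, int], ...] = (
    ("3-17", 3, 17),
    ("18-44", 18, 44),
    ("45-64", 45, 64),
    ("65-84", 65, 84),
    ("85+", 85, 99),
)

# Rules a near-miss can violate (one each).
RULE_KEYS = (
    "NUTRITION",
    "CHRONIC",
    "CONTINUOUS",
    "MALABSORPTION",
    "SBS_EVIDENCE",
    "ENROLLMENT",
    "AGE",
)


class Label(str, Enum):
    TRUE_CASE = "TRUE_CASE"
    NEAR_MISS = "NEAR_MISS"
    BACKGROUND = "BACKGROUND"


@dataclass(frozen=True)
class GroundTruthLabel:
    patient_id: str
    label: Label
    violated_rule: str | None = None
    qualifying_years: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if (self.violated_rule is not None) != (self.label is Label.NEAR_MISS):
            raise ValueError("violated_rule must be set iff label is NEAR_MISS")
        if bool(self.qualifying_years) != (self.label is Label.TRUE_CASE):
            raise ValueError("qualifying_years non-empty iff label is TRUE_CASE")


# Fictitious rule-code vocabulary; disjoint from background junk codes.
_RULE_CODES: dict[str, list[str]] = {
    PN: ["HCPCS:PN001", "HCPCS:PN002"],
    IV_HYDRATION: ["HCPCS:HYD01"],
    EN: ["HCPCS:EN001"],
    MALABSORPTION_DX: ["ICD10-DX:MAL01"],
    GI_SURGERY: ["ICD10-PCS:SURG1"],
    POST_SURGICAL_COMPLICATION: ["ICD10-DX:PSC01"],
    CONGENITAL_ABNORMALITY: ["ICD10-DX:CONG1"],
}

# Condition groupings (per-patient presence rates planted in true cases).
CONDITION_GROUP_CODES: dict[str, list[str]] = {
    "GI_DISORDERS": ["ICD10-DX:GIDX1"],
    "ABDOMINAL_PAIN": ["ICD10-DX:ABP01"],
    "FLUID_ELECTROLYTE": ["ICD10-DX:FLE01"],
}

MEDICATION_CLASS_CODES: dict[str, list[str]] = {
    "ANTIEMETICS": ["NDC:AE001"],
    "ANTIBIOTICS": ["NDC:AB001"],
    "OPIOIDS": ["NDC:OP001"],
}


def default_registry() -> CodeSetRegistry:
    """Registry over the generator's fictitious code vocabulary."""
    mapping: dict[str, list[str]] = {}
    mapping.update(_RULE_CODES)
    mapping.update(CONDITION_GROUP_CODES)
    mapping.update(MEDICATION_CLASS_CODES)
    return CodeSetRegistry.from_dict(mapping)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters for one synthetic database.

    Defaults mirror the emulated study: assessment years 2019-2021,
    nutrition supplies every 12-14 days (home supplies arrive every 1-2
    weeks), a roughly two-thirds-female cohort, and age-band proportions
    matching the described 2021 cohort.
    """

    seed: int = 0
    n_true_cases: int = 50
    n_near_misses_per_rule: int = 5
    n_background: int = 500
    study_years: tuple[int, ...] = (2019, 2020, 2021)
    supply_interval_days: tuple[int, int] = (12, 14)
    gender_mix: dict[str, float] = field(
        default_factory=lambda: {"FEMALE": 0.66, "MALE": 0.34}
    )
    age_band_mix: dict[str, float] = field(
        default_factory=lambda: {
            "3-17": 0.30,
            "18-44": 0.29,
            "45-64": 0.30,
            "65-84": 0.10,
            "85+": 0.01,
        }
    )
    # (year, age_band, gender) -> count of claim-free filler patients whose
    # enrollment covers exactly [Jan 1 (year-3), Dec 31 (year)].
    denominator_population: dict[tuple[int, str, str], int] = field(
        default_factory=dict
    )
    confuser_fraction: float = 0.2
    duplicate_claim_rate: float = 0.05
    iv_hydration_rate: float = 0.72
    en_rate: float = 0.43
    condition_group_rates: dict[str, float] = field(
        default_factory=lambda: {
            "GI_DISORDERS": 0.83,
            "ABDOMINAL_PAIN": 0.80,
            "FLUID_ELECTROLYTE": 0.72,
        }
    )
    medication_class_rates: dict[str, float] = field(
        default_factory=lambda: {
            "ANTIEMETICS": 0.70,
            "ANTIBIOTICS": 0.50,
            "OPIOIDS": 0.45,
        }
    )

    def __post_init__(self) -> None:
        for name, mix in (("gender_mix", self.gender_mix), ("age_band_mix", self.age_band_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1")
        if min(self.n_true_cases, self.n_near_misses_per_rule, self.n_background) < 0:
            raise ValueError("counts must be >= 0")
        lo, hi = self.supply_interval_days
        if lo < 5 or hi < lo:
            raise ValueError(
                "supply_interval_days must satisfy 5 <= min <= max so planted "
                "cases meet the 5-day spacing rule by construction"
            )
        if not self.study_years:
            raise ValueError("study_years must be non-empty")


def _patient_rng(seed: int, ordinal: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(ordinal,)))


def _choice(rng: np.random.Generator, mix: dict[str, float]) -> str:
    keys = sorted(mix)
    probs = np.array([mix[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


def _payer(rng: np.random.Generator) -> PayerChannel:
    return PayerChannel(
        _choice(
            rng,
            {"COMMERCIAL": 0.55, "MEDICARE": 0.20, "MEDICAID": 0.20, "OTHER": 0.05},
        )
    )


def _split_code(entry: str) -> tuple[CodeSystem, str]:
    system, _, code = entry.partition(":")
    return CodeSystem(system), code


def _claim(
    pid: str,
    when: date,
    entry: str,
    payer: PayerChannel,
    category: ClaimCategory = ClaimCategory.MEDICAL,
) -> ClaimRecord:
    system, code = _split_code(entry)
    return ClaimRecord(pid, when, code, system, category, payer)


def _birth_date_for_band(
    rng: np.random.Generator, band: str, reference_year: int, min_margin: int = 2
) -> date:
    """A birth date giving an in-band completed age at Jan 1 of the reference year.

    The age is drawn at least ``min_margin`` years above the band floor so
    the patient stays >= 3 years old at earlier study years; month/day are
    drawn after Jan 1 so the Jan-1 age equals the drawn age exactly.
    """
    lo, hi = next((l, h) for name, l, h in AGE_BANDS if name == band)
    lo = min(lo + min_margin, hi)
    age = int(rng.integers(lo, hi + 1))
    month = int(rng.integers(2, 13))
    day = int(rng.integers(1, 29))
    return date(reference_year - age - 1, month, day)


def _demographics(
    rng: np.random.Generator, pid: str, config: SyntheticConfig
) -> PatientDemographics:
    gender = Gender(_choice(rng, config.gender_mix))
    band = _choice(rng, config.age_band_mix)
    birth = _birth_date_for_band(rng, band, max(config.study_years))
    return PatientDemographics(pid, birth, gender)


def _supply_dates(
    rng: np.random.Generator, year: int, start_day: int, interval: tuple[int, int]
) -> list[date]:
    """Supply-claim dates covering a full calendar year at the given cadence."""
    lo, hi = interval
    current = date(year, 1, start_day)
    out = [current]
    while True:
        nxt = current + timedelta(days=int(rng.integers(lo, hi + 1)))
        if nxt.year != year:
            break
        out.append(nxt)
        current = nxt
    return out


def _enrollment_spans(
    rng: np.random.Generator, pid: str, start: date, end: date
) -> list[EnrollmentSpan]:
    """One continuous coverage interval, sometimes split into two touching spans."""
    if rng.random() < 0.3 and (end - start).days > 400:
        mid = start + timedelta(days=int(rng.integers(200, (end - start).days - 200)))
        return [
            EnrollmentSpan(pid, start, mid),
            EnrollmentSpan(pid, mid + timedelta(days=1), end),
        ]
    return [EnrollmentSpan(pid, start, end)]


def _maybe_duplicate(
    rng: np.random.Generator, claims: list[ClaimRecord], rate: float
) -> list[ClaimRecord]:
    out = list(claims)
    for c in claims:
        if rng.random() < rate:
            out.append(c)
    return out


def _true_case_parts(
    config: SyntheticConfig,
    rng: np.random.Generator,
    pid: str,
    target_years: frozenset[int],
    evidence_entry: str | None = None,
) -> tuple[list[ClaimRecord], list[EnrollmentSpan], PatientDemographics]:
    """Shared trajectory builder: surgery -> malabsorption -> supply cadence."""
    demo = _demographics(rng, pid, config)
    payer = _payer(rng)
    years = sorted(target_years)
    y0 = years[0]

    claims: list[ClaimRecord] = []
    # SBS evidence, then malabsorption, both strictly before the first
    # nutrition claim (which lands in early January of the first target year).
    surgery_date = date(y0 - 1, 11, int(rng.integers(1, 21)))
    if evidence_entry is None:
        if rng.random() < 0.8:
            evidence_entry = _RULE_CODES[GI_SURGERY][0]
        else:
            evidence_entry = _RULE_CODES[CONGENITAL_ABNORMALITY][0]
    claims.append(_claim(pid, surgery_date, evidence_entry, payer))
    mal_date = surgery_date + timedelta(days=int(rng.integers(10, 31)))
    claims.append(_claim(pid, mal_date, _RULE_CODES[MALABSORPTION_DX][0], payer))

    pn_entry = _RULE_CODES[PN][int(rng.integers(len(_RULE_CODES[PN])))]
    supply_dates: list[date] = []
    for y in years:
        supply_dates.extend(
            _supply_dates(rng, y, int(rng.integers(3, 9)), config.supply_interval_days)
        )
    claims.extend(_claim(pid, d, pn_entry, payer) for d in supply_dates)
    first_supply = min(supply_dates)

    if rng.random() < config.iv_hydration_rate:
        for off in (21, 130, 260):
            claims.append(
                _claim(
                    pid,
                    first_supply + timedelta(days=off),
                    _RULE_CODES[IV_HYDRATION][0],
                    payer,
                )
            )
    if rng.random() < config.en_rate:
        for off in (35, 180):
            claims.append(
                _claim(pid, first_supply + timedelta(days=off), _RULE_CODES[EN][0], payer)
            )
    for group, rate in config.condition_group_rates.items():
        if rng.random() < rate:
            when = first_supply + timedelta(days=int(rng.integers(30, 330)))
            claims.append(_claim(pid, when, CONDITION_GROUP_CODES[group][0], payer))
    for cls, rate in config.medication_class_rates.items():
        if rng.random() < rate:
            when = first_supply + timedelta(days=int(rng.integers(30, 330)))
            claims.append(
                _claim(
                    pid, when, MEDICATION_CLASS_CODES[cls][0], payer,
                    ClaimCategory.PHARMACY,
                )
            )

    claims = _maybe_duplicate(rng, claims, config.duplicate_claim_rate)
    claims.sort(key=lambda c: (c.service_date, c.code))

    # Coverage: previous-three-years window for every target year, the index
    # year plus two subsequent years, and the 2018-2021 global window.
    enroll_start = date(min(y0 - 3, 2018), 1, 1)
    enroll_end = date(max(y0 + 2, years[-1], 2021), 12, 31)
    spans = _enrollment_spans(rng, pid, enroll_start, enroll_end)
    return claims, spans, demo


def generate_true_case(
    config: SyntheticConfig,
    ordinal: int,
    target_years: frozenset[int] | set[int],
    patient_id: str | None = None,
) -> tuple[list[ClaimRecord], list[EnrollmentSpan], PatientDemographics, GroundTruthLabel]:
    """A patient satisfying every primary-definition rule in each target year."""
    target_years = frozenset(target_years)
    if not target_years or not target_years <= set(config.study_years):
        raise ValueError("target_years must be a non-empty subset of study_years")
    pid = patient_id or f"T{ordinal:05d}"
    rng = _patient_rng(config.seed, ordinal)
    claims, spans, demo = _true_case_parts(config, rng, pid, target_years)
    label = GroundTruthLabel(pid, Label.TRUE_CASE, None, target_years)
    return claims, spans, demo, label


def generate_near_miss(
    config: SyntheticConfig,
    ordinal: int,
    violated_rule: str,
    patient_id: str | None = None,
) -> tuple[list[ClaimRecord], list[EnrollmentSpan], PatientDemographics, GroundTruthLabel]:
    """A trajectory violating exactly the named rule.

    NUTRITION    — the supply cadence is billed as enteral nutrition, which
                   never counts toward the parenteral-support rules;
    CHRONIC      — twice-monthly claims over six consecutive months whose
                   overall span is < 183 days (continuous still passes);
    CONTINUOUS   — one claim per month for a full year;
    MALABSORPTION— malabsorption diagnosis dated after the first nutrition
                   claim (ordering violation);
    SBS_EVIDENCE — surgery dated after the first nutrition claim;
    ENROLLMENT   — a coverage gap inside the required enrollment window;
    AGE          — younger than 3 years in every study year.
    """
    if violated_rule not in RULE_KEYS:
        raise ValueError(f"unknown rule {violated_rule!r}; expected one of {RULE_KEYS}")
    pid = patient_id or f"N{ordinal:05d}"
    rng = _patient_rng(config.seed, ordinal)
    all_years = frozenset(config.study_years)
    y0 = min(config.study_years)
    payer = _payer(rng)

    if violated_rule == "NUTRITION":
        claims, spans, demo = _true_case_parts(config, rng, pid, all_years)
        en_system, en_code = _split_code(_RULE_CODES[EN][0])
        ps_pairs = _pairs(PN) | _pairs(IV_HYDRATION)
        claims = [
            replace(c, code=en_code, code_system=en_system)
            if (c.code_system, c.code) in ps_pairs
            else c
            for c in claims
        ]
    elif violated_rule == "CHRONIC":
        demo = _demographics(rng, pid, config)
        claims = [
            _claim(pid, date(y0 - 1, 11, 5), _RULE_CODES[GI_SURGERY][0], payer),
            _claim(pid, date(y0 - 1, 12, 1), _RULE_CODES[MALABSORPTION_DX][0], payer),
        ]
        for month in range(1, 7):
            d1 = int(rng.integers(1, 4))
            claims.append(_claim(pid, date(y0, month, d1), _RULE_CODES[PN][0], payer))
            d2 = d1 + int(rng.integers(10, 14))
            if month < 6:
                claims.append(
                    _claim(pid, date(y0, month, d2), _RULE_CODES[PN][0], payer)
                )
            else:
                # keep the overall span safely under 183 days
                claims.append(
                    _claim(pid, date(y0, 6, min(d2, 15)), _RULE_CODES[PN][0], payer)
                )
        claims.sort(key=lambda c: (c.service_date, c.code))
        spans = _enrollment_spans(
            rng, pid, date(min(y0 - 3, 2018), 1, 1), date(max(y0 + 2, 2021), 12, 31)
        )
    elif violated_rule == "CONTINUOUS":
        demo = _demographics(rng, pid, config)
        claims = [
            _claim(pid, date(y0 - 1, 11, 5), _RULE_CODES[GI_SURGERY][0], payer),
            _claim(pid, date(y0 - 1, 12, 1), _RULE_CODES[MALABSORPTION_DX][0], payer),
        ]
        for y in sorted(all_years):
            for month in range(1, 13):
                claims.append(
                    _claim(
                        pid,
                        date(y, month, int(rng.integers(5, 21))),
                        _RULE_CODES[PN][0],
                        payer,
                    )
                )
        claims.sort(key=lambda c: (c.service_date, c.code))
        spans = _enrollment_spans(
            rng, pid, date(min(y0 - 3, 2018), 1, 1),
            date(max(y0 + 2, max(all_years), 2021), 12, 31),
        )
    elif violated_rule == "MALABSORPTION":
        claims, spans, demo = _true_case_parts(config, rng, pid, all_years)
        first_ps = min(
            c.service_date
            for c in claims
            if (c.code_system, c.code) in _pairs(PN) | _pairs(IV_HYDRATION)
        )
        shift = first_ps + timedelta(days=int(rng.integers(30, 61)))
        claims = [
            replace(c, service_date=shift)
            if (c.code_system, c.code) in _pairs(MALABSORPTION_DX)
            else c
            for c in claims
        ]
        claims.sort(key=lambda c: (c.service_date, c.code))
    elif violated_rule == "SBS_EVIDENCE":
        claims, spans, demo = _true_case_parts(config, rng, pid, all_years)
        evidence_pairs = (
            _pairs(GI_SURGERY) | _pairs(POST_SURGICAL_COMPLICATION) | _pairs(CONGENITAL_ABNORMALITY)
        )
        first_ps = min(
            c.service_date
            for c in claims
            if (c.code_system, c.code) in _pairs(PN) | _pairs(IV_HYDRATION)
        )
        shift = first_ps + timedelta(days=int(rng.integers(30, 61)))
        claims = [
            replace(c, service_date=shift)
            if (c.code_system, c.code) in evidence_pairs
            else c
            for c in claims
        ]
        claims.sort(key=lambda c: (c.service_date, c.code))
    elif violated_rule == "ENROLLMENT":
        claims, spans, demo = _true_case_parts(config, rng, pid, all_years)
        start = min(s.start_date for s in spans)
        end = max(s.end_date for s in spans)
        gap_start = date(y0 + 1, 7, 1)
        gap_end = date(y0 + 1, 7, 31)
        spans = [
            EnrollmentSpan(pid, start, gap_start - timedelta(days=1)),
            EnrollmentSpan(pid, gap_end + timedelta(days=1), end),
        ]
    elif violated_rule == "AGE":
        claims, spans, demo = _true_case_parts(config, rng, pid, all_years)
        young_birth = date(max(config.study_years) - 2, 3, 1)
        demo = PatientDemographics(pid, young_birth, demo.gender, demo.race)
    label = GroundTruthLabel(pid, Label.NEAR_MISS, violated_rule, frozenset())
    return claims, spans, demo, label


def _pairs(category: str) -> frozenset[tuple[CodeSystem, str]]:
    return frozenset(_split_code(e) for e in _RULE_CODES[category])


_JUNK_CODES = [f"JUNK{i:02d}" for i in range(40)]


def generate_background(
    config: SyntheticConfig, ordinal: int, patient_id: str | None = None
) -> tuple[list[ClaimRecord], list[EnrollmentSpan], PatientDemographics, GroundTruthLabel]:
    """A non-case: junk claims, or a confuser reusing rule codes non-qualifyingly."""
    pid = patient_id or f"B{ordinal:05d}"
    rng = _patient_rng(config.seed, ordinal)
    payer = _payer(rng)
    demo = _demographics(rng, pid, config)
    y0, y_last = min(config.study_years), max(config.study_years)
    horizon_start = date(y0 - 3, 1, 1)
    horizon_end = date(max(y_last, 2021), 12, 31)
    horizon_days = (horizon_end - horizon_start).days

    def random_date() -> date:
        return horizon_start + timedelta(days=int(rng.integers(0, horizon_days + 1)))

    claims: list[ClaimRecord] = []
    if rng.random() < config.confuser_fraction:
        pattern = int(rng.integers(4))
        anchor = date(y0, 1, int(rng.integers(3, 9)))
        if pattern == 0:
            # single parenteral-support claim: fails the chronic rule
            claims.append(_claim(pid, anchor - timedelta(days=60), _RULE_CODES[GI_SURGERY][0], payer))
            claims.append(_claim(pid, anchor - timedelta(days=40), _RULE_CODES[MALABSORPTION_DX][0], payer))
            claims.append(_claim(pid, anchor, _RULE_CODES[PN][0], payer))
        elif pattern == 1:
            # three-month cadence only: fails chronic and continuous
            claims.append(_claim(pid, anchor - timedelta(days=60), _RULE_CODES[GI_SURGERY][0], payer))
            claims.append(_claim(pid, anchor - timedelta(days=40), _RULE_CODES[MALABSORPTION_DX][0], payer))
            d = anchor
            while d < anchor + timedelta(days=90):
                claims.append(_claim(pid, d, _RULE_CODES[PN][0], payer))
                d += timedelta(days=13)
        elif pattern == 2:
            # diagnosis/surgery history but no nutrition support at all
            claims.append(_claim(pid, random_date(), _RULE_CODES[GI_SURGERY][0], payer))
            claims.append(_claim(pid, random_date(), _RULE_CODES[MALABSORPTION_DX][0], payer))
        else:
            # enteral-only cadence: EN never counts toward eligibility
            d = anchor
            while d.year == anchor.year:
                claims.append(_claim(pid, d, _RULE_CODES[EN][0], payer))
                d += timedelta(days=13)
    else:
        n = int(rng.integers(0, 11))
        for _ in range(n):
            code = _JUNK_CODES[int(rng.integers(len(_JUNK_CODES)))]
            claims.append(
                ClaimRecord(pid, random_date(), code, CodeSystem.OTHER,
                            ClaimCategory.MEDICAL, payer)
            )
    claims.sort(key=lambda c: (c.service_date, c.code))

    if rng.random() < 0.5:
        spans = _enrollment_spans(rng, pid, horizon_start, horizon_end)
    else:
        a, b = sorted(
            (random_date(), random_date()), key=lambda d: d.toordinal()
        )
        spans = [EnrollmentSpan(pid, a, b)]

    # exercise the unknown-age / unknown-gender exclusions occasionally
    if rng.random() < 0.05:
        demo = PatientDemographics(pid, None, demo.gender, demo.race)
    if rng.random() < 0.05:
        demo = PatientDemographics(pid, demo.birth_date, Gender.UNKNOWN, demo.race)

    label = GroundTruthLabel(pid, Label.BACKGROUND)
    return claims, spans, demo, label


def _filler_patient(
    config: SyntheticConfig, ordinal: int, pid: str, year: int, band: str, gender: str
) -> tuple[list[EnrollmentSpan], PatientDemographics]:
    """Claim-free patient enrolled exactly [Jan 1 (year-3), Dec 31 (year)]."""
    rng = _patient_rng(config.seed, ordinal)
    lo, hi = next((l, h) for name, l, h in AGE_BANDS if name == band)
    age = int(rng.integers(lo, hi + 1))
    month = int(rng.integers(2, 13))
    day = int(rng.integers(1, 29))
    birth = date(year - age - 1, month, day)
    demo = PatientDemographics(pid, birth, Gender(gender))
    spans = [EnrollmentSpan(pid, date(year - 3, 1, 1), date(year, 12, 31))]
    return spans, demo


def _true_case_target_years(
    rng: np.random.Generator, study_years: tuple[int, ...]
) -> frozenset[int]:
    """Contiguous subset of the study years, biased toward the full run."""
    years = sorted(study_years)
    r = rng.random()
    if r < 0.6 or len(years) == 1:
        return frozenset(years)
    if r < 0.8:
        start = int(rng.integers(1, len(years)))
        return frozenset(years[start:])
    end = int(rng.integers(1, len(years)))
    return frozenset(years[:end])


def generate_database(
    config: SyntheticConfig,
) -> tuple[ClaimsDatabase, list[GroundTruthLabel]]:
    """Full synthetic database: true cases, near-misses, background, fillers.

    Patient ids are a seeded random permutation over the whole roster, so
    labels cannot be inferred from id order; the ground-truth labels are
    returned separately.
    """
    roster: list[tuple[str, int]] = []  # (kind marker, ordinal) placeholders
    n_total = (
        config.n_true_cases
        + len(RULE_KEYS) * config.n_near_misses_per_rule
        + config.n_background
        + sum(config.denominator_population.values())
    )
    master = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2**20,)))
    perm = master.permutation(n_total)
    ids = [f"P{int(k) + 1:06d}" for k in perm]

    claims: list[ClaimRecord] = []
    enrollment: list[EnrollmentSpan] = []
    demographics: list[PatientDemographics] = []
    labels: list[GroundTruthLabel] = []
    ordinal = 0

    for _ in range(config.n_true_cases):
        pid = ids[ordinal]
        years = _true_case_target_years(
            _patient_rng(config.seed, 2**21 + ordinal), config.study_years
        )
        c, s, d, lab = generate_true_case(config, ordinal, years, pid)
        claims += c
        enrollment += s
        demographics.append(d)
        labels.append(lab)
        ordinal += 1

    for rule in RULE_KEYS:
        for _ in range(config.n_near_misses_per_rule):
            pid = ids[ordinal]
            c, s, d, lab = generate_near_miss(config, ordinal, rule, pid)
            claims += c
            enrollment += s
            demographics.append(d)
            labels.append(lab)
            ordinal += 1

    for _ in range(config.n_background):
        pid = ids[ordinal]
        c, s, d, lab = generate_background(config, ordinal, pid)
        claims += c
        enrollment += s
        demographics.append(d)
        labels.append(lab)
        ordinal += 1

    for (year, band, gender), count in sorted(config.denominator_population.items()):
        for _ in range(count):
            pid = ids[ordinal]
            s, d = _filler_patient(config, ordinal, pid, year, band, gender)
            enrollment += s
            demographics.append(d)
            labels.append(GroundTruthLabel(pid, Label.BACKGROUND))
            ordinal += 1

    order = {pid: i for i, pid in enumerate(sorted(d.patient_id for d in demographics))}
    claims.sort(key=lambda c: (order[c.patient_id], c.service_date, c.code))
    enrollment.sort(key=lambda s: (order[s.patient_id], s.start_date))
    demographics.sort(key=lambda d: order[d.patient_id])
    labels.sort(key=lambda l: order[l.patient_id])
    db = ClaimsDatabase(claims, enrollment, demographics)
    return db, labels


# ---------------------------------------------------------------------------
# Near-miss repair (violation minimality helper)
# ---------------------------------------------------------------------------


def repair_near_miss(
    claims: list[ClaimRecord],
    enrollment: list[EnrollmentSpan],
    demographics: PatientDemographics,
    violated_rule: str,
) -> tuple[list[ClaimRecord], list[EnrollmentSpan], PatientDemographics]:
    """Flip the single violated feature so the trajectory passes the rules."""
    pid = demographics.patient_id
    claims = list(claims)
    if violated_rule == "NUTRITION":
        en_pairs = _pairs(EN)
        pn_system, pn_code = _split_code(_RULE_CODES[PN][0])
        claims = [
            replace(c, code=pn_code, code_system=pn_system)
            if (c.code_system, c.code) in en_pairs
            else c
            for c in claims
        ]
    elif violated_rule == "CHRONIC":
        ps = sorted(
            c.service_date
            for c in claims
            if (c.code_system, c.code) in _pairs(PN) | _pairs(IV_HYDRATION)
        )
        payer = claims[0].payer_channel
        claims.append(
            _claim(pid, ps[0] + timedelta(days=190), _RULE_CODES[PN][0], payer)
        )
    elif violated_rule == "CONTINUOUS":
        ps_pairs = _pairs(PN) | _pairs(IV_HYDRATION)
        by_month: dict[tuple[int, int], list[ClaimRecord]] = {}
        for c in claims:
            if (c.code_system, c.code) in ps_pairs:
                by_month.setdefault(
                    (c.service_date.year, c.service_date.month), []
                ).append(c)
        for (_, _), cs in by_month.items():
            if len(cs) == 1:
                c = cs[0]
                claims.append(
                    replace(c, service_date=c.service_date + timedelta(days=7))
                )
    elif violated_rule in ("MALABSORPTION", "SBS_EVIDENCE"):
        target_pairs = (
            _pairs(MALABSORPTION_DX)
            if violated_rule == "MALABSORPTION"
            else _pairs(GI_SURGERY)
            | _pairs(POST_SURGICAL_COMPLICATION)
            | _pairs(CONGENITAL_ABNORMALITY)
        )
        first_ps = min(
            c.service_date
            for c in claims
            if (c.code_system, c.code) in _pairs(PN) | _pairs(IV_HYDRATION)
        )
        offset = 30 if violated_rule == "MALABSORPTION" else 45
        claims = [
            replace(c, service_date=first_ps - timedelta(days=offset))
            if (c.code_system, c.code) in target_pairs
            else c
            for c in claims
        ]
    elif violated_rule == "ENROLLMENT":
        start = min(s.start_date for s in enrollment)
        end = max(s.end_date for s in enrollment)
        enrollment = [EnrollmentSpan(pid, start, end)]
    elif violated_rule == "AGE":
        birth = demographics.birth_date
        demographics = PatientDemographics(
            pid, date(birth.year - 10, birth.month, birth.day),
            demographics.gender, demographics.race,
        )
    else:
        raise ValueError(f"unknown rule {violated_rule!r}")
    claims.sort(key=lambda c: (c.service_date, c.code))
    return claims, enrollment, demographics


# ---------------------------------------------------------------------------
# Marginal-constrained cohort stand-in
# ---------------------------------------------------------------------------


def synthetic_cohort_from_marginals(
    total: int,
    female: int,
    age_band_counts: dict[str, int],
    only_pn: int,
    pn_iv: int,
    pn_en: int,
    pn_en_iv: int,
    at_least_en: int,
    at_least_iv: int,
    year: int = 2021,
):
    """Synthetic stand-in cohort constructed to match published marginal counts.

    Builds ``total`` cohort members plus a minimal claims database whose
    gender, age-band, and nutrition-code-combination tabulations reproduce
    the supplied marginals exactly.  The joint assignment across
    characteristics is arbitrary (marginals do not determine it); the
    non-PN combination cells are completed with the minimal-overlap solution
    of the two "at least one" constraints.

    Returns ``(members, db)`` ready for the characterization tables.
    """
    from .cohort_engine import CohortMember

    if sum(age_band_counts.values()) != total:
        raise ValueError("age band counts must sum to total")
    if not 0 <= female <= total:
        raise ValueError("female count out of range")

    # complete the non-PN cells: EN&IV overlap c, EN-only a, IV-only b, none d
    r1 = at_least_en - pn_en - pn_en_iv
    r2 = at_least_iv - pn_iv - pn_en_iv
    non_pn = total - (only_pn + pn_iv + pn_en + pn_en_iv)
    if min(r1, r2, non_pn) < 0:
        raise ValueError("inconsistent nutrition-combination marginals")
    c = max(0, r1 + r2 - non_pn)
    a, b = r1 - c, r2 - c
    d = non_pn - a - b - c
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent nutrition-combination marginals")

    combos = (
        [frozenset({PN})] * only_pn
        + [frozenset({PN, IV_HYDRATION})] * pn_iv
        + [frozenset({PN, EN})] * pn_en
        + [frozenset({PN, EN, IV_HYDRATION})] * pn_en_iv
        + [frozenset({EN, IV_HYDRATION})] * c
        + [frozenset({EN})] * a
        + [frozenset({IV_HYDRATION})] * b
        + [frozenset()] * d
    )
    rep_age = {"3-17": 10, "18-44": 30, "45-64": 55, "65-84": 75, "85+": 90}
    ages = [
        rep_age[band]
        for band, count in age_band_counts.items()
        for _ in range(count)
    ]

    members, claims, demographics = [], [], []
    for i in range(total):
        pid = f"S{i:05d}"
        gender = Gender.FEMALE if i < female else Gender.MALE
        age = ages[i]
        birth = date(year - age - 1, 6, 15)
        demographics.append(PatientDemographics(pid, birth, gender))
        members.append(
            CohortMember(
                patient_id=pid,
                index_date=date(year, 2, 1),
                qualifying_years=frozenset({year}),
                definition_name="primary",
                age_at_index=age,
                age_at_year_start=age,
                gender=gender,
            )
        )
        for category in combos[i]:
            claims.append(
                _claim(pid, date(year, 3, 1), _RULE_CODES[category][0],
                       PayerChannel.COMMERCIAL)
            )
    db = ClaimsDatabase(claims, [], demographics)
    return members, db


# ---------------------------------------------------------------------------
# Label I/O and database serialization
# ---------------------------------------------------------------------------


def write_labels(labels: list[GroundTruthLabel], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": l.patient_id,
                "label": l.label.value,
                "violated_rule": l.violated_rule or "",
                "qualifying_years": "|".join(map(str, sorted(l.qualifying_years))),
            }
            for l in labels
        ],
        columns=["patient_id", "label", "violated_rule", "qualifying_years"],
    ).to_csv(path, index=False)


def read_labels(path: str | Path) -> list[GroundTruthLabel]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        GroundTruthLabel(
            row.patient_id,
            Label(row.label),
            row.violated_rule or None,
            frozenset(
                int(y) for y in row.qualifying_years.split("|") if y
            ),
        )
        for row in df.itertuples(index=False)
    ]


def write_database(
    db: ClaimsDatabase,
    labels: list[GroundTruthLabel],
    out_dir: str | Path,
    registry: CodeSetRegistry | None = None,
) -> dict[str, Path]:
    """Write claims/enrollment/demographics/labels (and registry) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "claims": out / "claims.csv",
        "enrollment": out / "enrollment.csv",
        "demographics": out / "demographics.csv",
        "labels": out / "labels.csv",
    }
    write_claims_database(
        db, paths["claims"], paths["enrollment"], paths["demographics"]
    )
    write_labels(labels, paths["labels"])
    if registry is not None:
        paths["registry"] = out / "registry.yaml"
        registry.to_yaml(paths["registry"])
    return paths
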