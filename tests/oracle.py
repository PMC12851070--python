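"""Independent brute-force cohort checker used as a test oracle.

Deliberately naive and structurally different from the engine: every rule
is tested by exhaustive date enumeration (all claim-date pairs, all
candidate month runs, all within-month claim combinations) and enrollment
coverage by materializing the set of covered days.  No engine helper
(greedy thinning, span merging, month indexing) is reused.
"""

from __future__ import annotations

from datetime import date, timedelta
from itertools import combinations

from sbsif_claims.data_model import ClaimsDatabase, Gender


def _code_pairs(registry, keys):
    pairs = set()
    for key in keys:
        pairs |= set(registry.codes(key))
    return pairs


def _claim_dates(claims, pairs, since=None):
    dates = sorted(
        {
            c.service_date
            for c in claims
            if (c.code_system, c.code) in pairs
            and (since is None or c.service_date >= since)
        }
    )
    return dates


def _month_has_spaced_claims(dates, year, month, need, spacing):
    in_month = sorted({d for d in dates if d.year == year and d.month == month})
    for combo in combinations(in_month, need):
        if all(
            (b - a).days >= spacing for a, b in combinations(sorted(combo), 2)
        ):
            return True
    return False


def _covered_days(spans):
    days = set()
    for s in spans:
        d = s.start_date
        while d <= s.end_date:
            days.add(d)
            d += timedelta(days=1)
    return days


def _interval_covered(days, start, end):
    d = start
    while d <= end:
        if d not in days:
            return False
        d += timedelta(days=1)
    return True


def brute_force_cohort(
    db: ClaimsDatabase, registry, definition, year: int
) -> set[str]:
    """Patient ids passing every rule of ``definition`` for ``year``."""
    nutrition_pairs = _code_pairs(registry, definition.nutrition_categories)
    mal_pairs = _code_pairs(registry, ["MALABSORPTION_DX"])
    evidence_pairs = _code_pairs(
        registry,
        ["GI_SURGERY", "POST_SURGICAL_COMPLICATION", "CONGENITAL_ABNORMALITY"],
    )
    included = set()
    for pid in db.patients():
        claims = db.claims_for(pid)
        demo = db.demographics_for(pid)

        nut = _claim_dates(claims, nutrition_pairs, definition.lookback_start)
        if len(nut) < definition.min_initial_nutrition_claims:
            continue
        first_ps = nut[0]

        if definition.require_chronic:
            if not any(
                abs((a - b).days) >= definition.chronic_gap_days
                for a, b in combinations(nut, 2)
            ):
                continue

        if definition.require_continuous:
            need = definition.continuous_min_claims_per_month
            spacing = definition.continuous_min_spacing_days
            run = definition.continuous_min_months
            ok = False
            if definition.continuous_window.value == "calendar_year":
                for start in range(1, 13 - run + 1):
                    if all(
                        _month_has_spaced_claims(nut, year, start + k, need, spacing)
                        for k in range(run)
                    ):
                        ok = True
                        break
            else:
                candidates = [
                    (y, m)
                    for y in (year - 1, year, year + 1)
                    for m in range(1, 13)
                ]
                for i in range(len(candidates) - run + 1):
                    window = candidates[i : i + run]
                    if not any(y == year for y, _ in window):
                        continue
                    if all(
                        _month_has_spaced_claims(nut, y, m, need, spacing)
                        for y, m in window
                    ):
                        ok = True
                        break
            if not ok:
                continue

        if definition.require_malabsorption:
            mal = _claim_dates(claims, mal_pairs)
            if not any(d < first_ps for d in mal):
                continue

        evid = _claim_dates(claims, evidence_pairs)
        if definition.require_sbs_evidence:
            if not any(d < first_ps for d in evid):
                continue

        if evid:
            after = [d for d in nut if d > min(evid)]
            if not after:
                continue
            index_date = after[0]
        elif definition.require_sbs_evidence:
            continue
        else:
            index_date = first_ps

        days = _covered_days(
            [s for s in db.enrollment if s.patient_id == pid]
        )
        idx_start = date(index_date.year, 1, 1)
        idx_end = date(
            index_date.year + definition.enrollment_years_after_index, 12, 31
        )
        g_start, g_end = definition.global_window
        if not _interval_covered(days, idx_start, idx_end):
            continue
        if not _interval_covered(days, g_start, g_end):
            continue

        if demo.birth_date is None or demo.gender is Gender.UNKNOWN:
            continue
        jan1 = date(year, 1, 1)
        age = jan1.year - demo.birth_date.year
        if (jan1.month, jan1.day) < (demo.birth_date.month, demo.birth_date.day):
            age -= 1
        if age < definition.min_age_years:
            continue

        included.add(pid)
    return included
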