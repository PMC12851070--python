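"""Inclusion-rule checks and cohort construction."""

import itertools
from datetime import date

import pytest

from sbsif_claims.cohort_engine import (
    RULE_SEQUENCE,
    ContinuousWindow,
    alternative_1,
    alternative_2,
    assign_index_date,
    build_cohort,
    check_chronic,
    check_continuous,
    check_enrollment,
    check_malabsorption_prior,
    check_nutrition_requirement,
    check_sbs_evidence,
    get_definition,
    primary_definition,
    thin_dates,
)
from sbsif_claims.data_model import (
    ClaimRecord,
    ClaimsDatabase,
    CodeSystem,
    EnrollmentSpan,
    Gender,
    PatientDemographics,
)
from sbsif_claims.synthetic import Label, SyntheticConfig, generate_database

from oracle import brute_force_cohort


def _claim(day, code, system=CodeSystem.HCPCS):
    return ClaimRecord("P1", day, code, system)


PN_CLAIM = lambda d: _claim(d, "PN001")
IV_CLAIM = lambda d: _claim(d, "HYD01")
MAL_CLAIM = lambda d: _claim(d, "MAL01", CodeSystem.ICD10_DX)
SURG_CLAIM = lambda d: _claim(d, "SURG1", CodeSystem.ICD10_PCS)
CONG_CLAIM = lambda d: _claim(d, "CONG1", CodeSystem.ICD10_DX)


class TestNutritionRequirement:
    def test_single_iv_hydration_claim_passes_primary(self, registry):
        ok, first = check_nutrition_requirement(
            [IV_CLAIM(date(2020, 3, 1))], registry, primary_definition()
        )
        assert ok and first == date(2020, 3, 1)

    def test_iv_hydration_does_not_satisfy_pn_only_definition(self, registry):
        ok, first = check_nutrition_requirement(
            [IV_CLAIM(date(2020, 3, 1))], registry, alternative_1()
        )
        assert not ok and first is None

    def test_claims_before_lookback_are_ignored(self, registry):
        ok, _ = check_nutrition_requirement(
            [PN_CLAIM(date(2015, 12, 31))], registry, primary_definition()
        )
        assert not ok


class TestChronic:
    @pytest.mark.parametrize(
        "dates, expected",
        [
            ([date(2020, 1, 1)], False),  # a single claim is never chronic
            ([date(2020, 1, 1), date(2020, 7, 2)], True),  # exactly 183 days
            ([date(2020, 1, 1), date(2020, 7, 1)], False),  # 182 days
        ],
    )
    def test_six_month_boundary(self, dates, expected):
        assert check_chronic(dates, 183) is expected


class TestContinuous:
    def test_twice_monthly_all_year_passes(self):
        dates = [date(2020, m, d) for m in range(1, 13) for d in (1, 15)]
        assert check_continuous(dates, 2020, primary_definition())

    def test_three_day_spacing_fails(self):
        dates = [date(2020, m, d) for m in range(1, 13) for d in (1, 4)]
        assert not check_continuous(dates, 2020, primary_definition())

    def test_five_qualifying_months_fail(self):
        dates = [date(2020, m, d) for m in range(1, 6) for d in (1, 15)]
        assert not check_continuous(dates, 2020, primary_definition())

    def test_rolling_window_may_straddle_year_boundary(self):
        # Oct 2019 - Mar 2020: fails the calendar-year reading, passes rolling
        dates = [date(2019, m, d) for m in (10, 11, 12) for d in (1, 15)]
        dates += [date(2020, m, d) for m in (1, 2, 3) for d in (1, 15)]
        assert not check_continuous(dates, 2020, primary_definition())
        rolling = primary_definition().with_options(
            continuous_window=ContinuousWindow.ROLLING_6_MONTHS
        )
        assert check_continuous(dates, 2020, rolling)

    def test_thinning_collapses_same_day_and_close_claims(self):
        dates = [date(2020, 1, 1), date(2020, 1, 3), date(2020, 1, 6), date(2020, 1, 11)]
        assert thin_dates(dates, 5) == [date(2020, 1, 1), date(2020, 1, 6), date(2020, 1, 11)]


class TestTemporalOrdering:
    def test_malabsorption_day_before_first_ps_passes(self, registry):
        claims = [MAL_CLAIM(date(2020, 2, 28)), PN_CLAIM(date(2020, 3, 1))]
        assert check_malabsorption_prior(claims, registry, date(2020, 3, 1))

    def test_same_day_fails_strict_before_but_passes_lenient(self, registry):
        claims = [MAL_CLAIM(date(2020, 3, 1))]
        assert not check_malabsorption_prior(claims, registry, date(2020, 3, 1))
        assert check_malabsorption_prior(
            claims, registry, date(2020, 3, 1), allow_same_day=True
        )

    def test_congenital_arm_satisfies_evidence(self, registry):
        claims = [CONG_CLAIM(date(2005, 6, 1))]
        ok, earliest = check_sbs_evidence(claims, registry, date(2020, 3, 1))
        assert ok and earliest == date(2005, 6, 1)

    def test_surgery_after_first_ps_fails(self, registry):
        claims = [SURG_CLAIM(date(2020, 5, 1))]
        ok, earliest = check_sbs_evidence(claims, registry, date(2020, 3, 1))
        assert not ok and earliest is None

    def test_two_evidence_arms_return_earliest(self, registry):
        claims = [SURG_CLAIM(date(2019, 6, 1)), CONG_CLAIM(date(2010, 1, 1))]
        ok, earliest = check_sbs_evidence(claims, registry, date(2020, 3, 1))
        assert ok and earliest == date(2010, 1, 1)


class TestIndexDate:
    def test_index_is_first_nutrition_after_surgery(self, registry):
        claims = [
            SURG_CLAIM(date(2020, 3, 1)),
            PN_CLAIM(date(2020, 4, 1)),
            PN_CLAIM(date(2020, 5, 1)),
        ]
        assert assign_index_date(claims, registry, primary_definition()) == date(2020, 4, 1)

    def test_nutrition_only_before_surgery_is_ineligible(self, registry):
        claims = [PN_CLAIM(date(2020, 1, 1)), SURG_CLAIM(date(2020, 3, 1))]
        assert assign_index_date(claims, registry, primary_definition()) is None

    def test_same_day_duplicate_claims_collapse(self, registry):
        claims = [
            SURG_CLAIM(date(2020, 3, 1)),
            PN_CLAIM(date(2020, 4, 1)),
            PN_CLAIM(date(2020, 4, 1)),
        ]
        assert assign_index_date(claims, registry, primary_definition()) == date(2020, 4, 1)


class TestEnrollment:
    def test_superset_span_passes(self):
        spans = [EnrollmentSpan("P1", date(2016, 1, 1), date(2022, 12, 31))]
        assert check_enrollment(spans, date(2019, 5, 1), primary_definition())

    def test_gap_inside_required_window_fails(self):
        spans = [
            EnrollmentSpan("P1", date(2016, 1, 1), date(2020, 6, 30)),
            EnrollmentSpan("P1", date(2020, 8, 1), date(2022, 12, 31)),
        ]
        assert not check_enrollment(spans, date(2019, 5, 1), primary_definition())

    def test_global_window_is_also_required(self):
        # covers the 3-year index window but not the 2018-2021 study window
        spans = [EnrollmentSpan("P1", date(2019, 1, 1), date(2021, 12, 31))]
        assert not check_enrollment(spans, date(2019, 5, 1), primary_definition())


class TestBuildCohort:
    def test_empty_database_gives_empty_cohort_and_zero_waterfall(self, registry):
        db = ClaimsDatabase([], [], [])
        members, waterfall = build_cohort(db, registry, primary_definition(), 2021)
        assert members == []
        assert all(n == 0 for _, n in waterfall.steps)

    def test_planted_true_cases_recovered_exactly(self, registry, small_db):
        db, labels = small_db
        for year in (2019, 2020, 2021):
            members, _ = build_cohort(db, registry, primary_definition(), year)
            expected = {
                l.patient_id
                for l in labels
                if l.label is Label.TRUE_CASE and year in l.qualifying_years
            }
            assert {m.patient_id for m in members} == expected

    def test_alt2_is_a_superset_including_malabsorption_near_misses(
        self, registry, small_db
    ):
        db, labels = small_db
        primary, _ = build_cohort(db, registry, primary_definition(), 2021)
        alt2, _ = build_cohort(db, registry, alternative_2(), 2021)
        primary_ids = {m.patient_id for m in primary}
        alt2_ids = {m.patient_id for m in alt2}
        assert primary_ids <= alt2_ids
        mal = {l.patient_id for l in labels if l.violated_rule == "MALABSORPTION"}
        assert mal <= alt2_ids and mal.isdisjoint(primary_ids)

    def test_waterfall_counts_never_increase(self, registry, small_db):
        db, _ = small_db
        _, waterfall = build_cohort(db, registry, primary_definition(), 2020)
        counts = [n for _, n in waterfall.steps]
        assert counts == sorted(counts, reverse=True)
        assert waterfall.steps[0] == ("candidates", db.n_patients)

    def test_rule_order_changes_waterfall_not_membership(self, registry, small_db):
        db, _ = small_db
        baseline, _ = build_cohort(db, registry, primary_definition(), 2021)
        base_ids = {m.patient_id for m in baseline}
        orders = itertools.islice(itertools.permutations(RULE_SEQUENCE), 0, 24, 7)
        for order in orders:
            members, _ = build_cohort(
                db, registry, primary_definition(), 2021, rule_order=order
            )
            assert {m.patient_id for m in members} == base_ids

    def test_members_carry_index_age_and_gender(self, registry, small_db):
        db, _ = small_db
        members, _ = build_cohort(db, registry, primary_definition(), 2021)
        for m in members:
            assert m.index_date is not None
            assert m.age_at_year_start >= 3
            assert m.gender in (Gender.FEMALE, Gender.MALE)

    def test_unknown_definition_name_raises(self):
        with pytest.raises(KeyError):
            get_definition("tertiary")


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_engine_matches_brute_force_checker(self, registry, seed):
        config = SyntheticConfig(
            seed=seed, n_true_cases=6, n_near_misses_per_rule=2, n_background=40
        )
        db, _ = generate_database(config)
        for year in (2019, 2021):
            for definition in (primary_definition(), alternative_2()):
                members, _ = build_cohort(db, registry, definition, year)
                assert {m.patient_id for m in members} == brute_force_cohort(
                    db, registry, definition, year
                )


def test_determinism_identical_inputs_identical_outputs(registry, small_db):
    db, _ = small_db
    a = build_cohort(db, registry, primary_definition(), 2020)
    b = build_cohort(db, registry, primary_definition(), 2020)
    assert a[0] == b[0]
    assert a[1].steps == b[1].steps
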