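"""Stratified rates, census projection, and derived growth/per-million metrics."""

from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sbsif_claims.cohort_engine import CohortMember, build_cohort, primary_definition
from sbsif_claims.data_model import (
    ClaimsDatabase,
    EnrollmentSpan,
    Gender,
    PatientDemographics,
)
from sbsif_claims.projection import (
    ProjectionError,
    StratumRate,
    compute_stratum_rates,
    denominator_counts,
    growth_metrics,
    per_million,
    project_to_population,
    read_census,
    write_census,
)
from sbsif_claims.synthetic import SyntheticConfig, generate_database


def _member(pid, age, gender):
    return CohortMember(
        patient_id=pid,
        index_date=date(2021, 2, 1),
        qualifying_years=frozenset({2021}),
        definition_name="primary",
        age_at_index=age,
        age_at_year_start=age,
        gender=gender,
    )


def _enrolled_patient(pid, age, gender):
    """Patient continuously enrolled 2018-2021, the 2021 denominator window."""
    birth = date(2021 - age - 1, 6, 15)
    return (
        PatientDemographics(pid, birth, gender),
        EnrollmentSpan(pid, date(2018, 1, 1), date(2021, 12, 31)),
    )


def _toy_db(n_female_18_44=20, n_male_45plus=10):
    demos, spans = [], []
    for i in range(n_female_18_44):
        d, s = _enrolled_patient(f"F{i}", 30, Gender.FEMALE)
        demos.append(d)
        spans.append(s)
    for i in range(n_male_45plus):
        d, s = _enrolled_patient(f"M{i}", 60, Gender.MALE)
        demos.append(d)
        spans.append(s)
    return ClaimsDatabase([], spans, demos)


class TestStratumRates:
    def test_single_cell_concentration(self):
        db = _toy_db()
        cohort = [_member(f"F{i}", 30, Gender.FEMALE) for i in range(6)]
        with pytest.warns(UserWarning):
            rates = compute_stratum_rates(cohort, db, 2021)
        by_cell = {(r.age_group, r.gender): r for r in rates}
        cell = by_cell[("18-44", Gender.FEMALE)]
        assert cell.numerator == 6 and cell.denominator == 20
        assert cell.rate == pytest.approx(0.3)
        other = by_cell[("45plus", Gender.MALE)]
        assert other.numerator == 0

    def test_rate_of_one_at_upper_bound(self):
        db = _toy_db(n_female_18_44=4)
        cohort = [_member(f"F{i}", 30, Gender.FEMALE) for i in range(4)]
        with pytest.warns(UserWarning):
            rates = compute_stratum_rates(cohort, db, 2021)
        cell = {(r.age_group, r.gender): r for r in rates}[("18-44", Gender.FEMALE)]
        assert cell.rate == 1.0

    def test_rates_match_hand_recount_on_synthetic_db(self, registry):
        config = SyntheticConfig(seed=21, n_true_cases=10, n_near_misses_per_rule=1,
                                 n_background=60)
        db, _ = generate_database(config)
        members, _ = build_cohort(db, registry, primary_definition(), 2021)
        rates = compute_stratum_rates(members, db, 2021)
        # independent recount of one cell
        for r in rates:
            n = sum(
                1
                for m in members
                if m.gender is r.gender
                and (
                    (r.age_group == "3-17" and 3 <= m.age_at_year_start <= 17)
                    or (r.age_group == "18-44" and 18 <= m.age_at_year_start <= 44)
                    or (r.age_group == "45plus" and m.age_at_year_start >= 45)
                )
            )
            assert r.numerator == n
            assert r.rate == pytest.approx(n / r.denominator)

    def test_numerator_cannot_exceed_denominator(self):
        with pytest.raises(ValueError):
            StratumRate(2021, "18-44", Gender.FEMALE, 5, 4, 1.25)


class TestProjection:
    def test_single_stratum_arithmetic(self):
        rates = [StratumRate(2021, "18-44", Gender.FEMALE, 6, 1000, 0.006)]
        census = {(2021, "18-44", "FEMALE"): 1_000_000}
        result = project_to_population(rates, census, 2021)
        assert result.total == 6000
        assert result.stratum_counts[("18-44", Gender.FEMALE)] == 6000

    def test_two_stratum_hand_arithmetic(self):
        rates = [
            StratumRate(2021, "18-44", Gender.FEMALE, 2, 2000, 0.001),
            StratumRate(2021, "45plus", Gender.MALE, 1, 500, 0.002),
        ]
        census = {
            (2021, "18-44", "FEMALE"): 2_000_000,
            (2021, "45plus", "MALE"): 500_000,
        }
        result = project_to_population(rates, census, 2021)
        assert result.total == 2000 + 1000 == 3000

    def test_identity_projection_recovers_cohort_counts(self, registry):
        """Census equal to database denominators reproduces raw cohort sizes."""
        config = SyntheticConfig(seed=8, n_true_cases=12, n_near_misses_per_rule=1,
                                 n_background=50)
        db, _ = generate_database(config)
        for year in (2019, 2021):
            members, _ = build_cohort(db, registry, primary_definition(), year)
            rates = compute_stratum_rates(members, db, year)
            census = {
                (year, g, s.value): n
                for (g, s), n in denominator_counts(db, year).items()
            }
            result = project_to_population(rates, census, year)
            assert result.total == len(members)
            assert result.total_unrounded == pytest.approx(len(members))

    def test_scale_equivariance_and_per_million_invariance(self, registry):
        config = SyntheticConfig(seed=8, n_true_cases=12, n_near_misses_per_rule=1,
                                 n_background=50)
        db, _ = generate_database(config)
        members, _ = build_cohort(db, registry, primary_definition(), 2021)
        rates = compute_stratum_rates(members, db, 2021)
        base = {
            (2021, g, s.value): n * 1000
            for (g, s), n in denominator_counts(db, 2021).items()
        }
        r1 = project_to_population(rates, base, 2021)
        for k in (2, 5):
            scaled = {key: pop * k for key, pop in base.items()}
            rk = project_to_population(rates, scaled, 2021)
            assert abs(rk.total - k * r1.total) <= 0.5 * k * len(rates)
            assert rk.per_million == r1.per_million

    def test_refining_a_stratum_preserves_the_total(self):
        rates = [StratumRate(2021, "45plus", Gender.MALE, 4, 1000, 0.004)]
        census = {(2021, "45plus", "MALE"): 600_000}
        whole = project_to_population(rates, census, 2021)
        split_rates = [
            StratumRate(2021, "45-64", Gender.MALE, 2, 500, 0.004),
            StratumRate(2021, "65plus", Gender.MALE, 2, 500, 0.004),
        ]
        split_census = {
            (2021, "45-64", "MALE"): 400_000,
            (2021, "65plus", "MALE"): 200_000,
        }
        split = project_to_population(split_rates, split_census, 2021)
        assert abs(split.total - whole.total) <= 1

    def test_missing_census_stratum_names_the_cell(self):
        rates = [StratumRate(2021, "18-44", Gender.FEMALE, 6, 1000, 0.006)]
        with pytest.raises(ProjectionError, match="18-44"):
            project_to_population(rates, {}, 2021)

    def test_census_round_trip(self, tmp_path):
        census = {(2021, "18-44", "FEMALE"): 123, (2019, "3-17", "MALE"): 456}
        path = tmp_path / "census.csv"
        write_census(census, path)
        assert read_census(path) == census


class TestDerivedMetrics:
    def test_overall_growth_from_annual_totals(self):
        g = growth_metrics({2019: 9450, 2020: 10824, 2021: 11803})
        assert g.overall_pct == pytest.approx(24.9)
        assert g.overall_pct > 24
        assert g.year_on_year_pct[2021] == pytest.approx(9.0)
        assert g.year_on_year_pct[2020] == pytest.approx(14.5)

    def test_equal_totals_give_zero_growth(self):
        g = growth_metrics({2019: 100, 2020: 100})
        assert g.overall_pct == 0.0

    def test_zero_baseline_is_undefined(self):
        g = growth_metrics({2019: 0, 2020: 100})
        assert g.overall_pct is None
        assert 2020 not in g.year_on_year_pct

    def test_single_year_rejected(self):
        with pytest.raises(ValueError):
            growth_metrics({2021: 100})

    @pytest.mark.parametrize(
        "total, population, expected",
        [
            (11803, 331_900_000, 36),
            (0, 1_000_000, 0),
            (1, 1_000_000, 1),
        ],
    )
    def test_per_million(self, total, population, expected):
        assert per_million(total, population) == expected

    @settings(deadline=None, max_examples=50)
    @given(
        total=st.integers(0, 10**6),
        population=st.integers(1, 10**9),
        k=st.integers(1, 100),
    )
    def test_per_million_scale_relation(self, total, population, k):
        """Scaling cases and population together leaves the rate unchanged."""
        assert per_million(total * k, population * k) == per_million(total, population)
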