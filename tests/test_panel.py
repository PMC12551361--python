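"""Survey harmonization: age/cohort arithmetic, validation, GDP joins."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dementia_cohorts.panel import (
    ELSA,
    HRS,
    SHARE,
    CoverageError,
    GDPSeries,
    PanelValidationError,
    SurveyDialect,
    attach_gdp,
    bin_age_group,
    bin_cohort,
    compute_age,
    filter_eligible,
    read_panel,
    write_panel,
)

# ---------------------------------------------------------------------------
# age / cohort arithmetic
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "interview_year, birth_year, expected",
    [(1994, 1923, 71), (2004, 1919, 85), (2000, 2000, 0)],
)
def test_compute_age_is_exact_year_difference(interview_year, birth_year, expected):
    assert compute_age(interview_year, birth_year) == expected


def test_compute_age_rejects_interview_before_birth():
    with pytest.raises(ValueError):
        compute_age(1920, 1930)


@pytest.mark.parametrize(
    "age, group",
    [(71, 1), (75, 1), (76, 2), (85, 3), (90, 4), (95, 5), (96, 6), (103, 6)],
)
def test_age_group_bins(age, group):
    assert bin_age_group(age) == group


def test_age_70_is_ineligible():
    assert bin_age_group(70) is None
    assert bin_age_group(0) is None


def test_age_group_rejects_bad_input():
    with pytest.raises(ValueError):
        bin_age_group(-3)
    with pytest.raises(ValueError):
        bin_age_group(71.5)


@given(st.integers(min_value=71, max_value=130))
@settings(max_examples=60, deadline=None)
def test_every_eligible_age_has_exactly_one_group(age):
    groups = [
        g
        for g, (lo, hi) in enumerate(
            [(71, 75), (76, 80), (81, 85), (86, 90), (91, 95), (96, float("inf"))],
            start=1,
        )
        if lo <= age <= hi
    ]
    assert groups == [bin_age_group(age)]


def test_dialect_cohort_bin_counts():
    assert len(HRS.cohort_bins) == 8
    assert len(SHARE.cohort_bins) == 7
    assert len(ELSA.cohort_bins) == 7
    assert HRS.reference_cohort == "1890-1913"
    assert SHARE.reference_cohort == "1901-1918"
    assert ELSA.reference_cohort == "1908-1918"


@pytest.mark.parametrize(
    "birth_year, dialect, label",
    [
        (1890, HRS, "1890-1913"),
        (1913, HRS, "1890-1913"),
        (1918, SHARE, "1901-1918"),
        (1908, ELSA, "1908-1918"),
        (1923, HRS, "1919-1923"),
        (1948, HRS, "1944-1948"),
    ],
)
def test_cohort_bins_contain_their_years(birth_year, dialect, label):
    assert bin_cohort(birth_year, dialect) == label


def test_birth_year_beyond_last_bin_is_out_of_range():
    for dialect in (HRS, SHARE, ELSA):
        assert bin_cohort(1950, dialect) is None
    assert bin_cohort(1889, HRS) is None


@pytest.mark.parametrize("dialect", [HRS, SHARE, ELSA], ids=lambda d: d.name)
def test_cohort_bins_partition_their_span(dialect):
    lo = dialect.cohort_bins[0][0]
    hi = dialect.cohort_bins[-1][1]
    for year in range(lo, hi + 1):
        hits = [
            label
            for (blo, bhi), label in zip(dialect.cohort_bins, dialect.cohort_labels)
            if blo <= year <= bhi
        ]
        assert len(hits) == 1
        assert bin_cohort(year, dialect) == hits[0]


def test_age_cohort_year_table_diagonals():
    """5-year birth cohorts shift one age group per 5 calendar years.

    For survey years 1994..2019 in 5-year steps, every birth year in the
    cohort bin printed for an age group lands in exactly that group.
    """
    years = [1994, 1999, 2004, 2009, 2014, 2019]
    for col, year in enumerate(years):
        for group, (age_lo, age_hi) in enumerate(
            [(71, 75), (76, 80), (81, 85), (86, 90), (91, 95)], start=1
        ):
            cohort_hi = year - age_lo
            cohort_lo = year - age_hi
            for birth in range(cohort_lo, cohort_hi + 1):
                assert bin_age_group(compute_age(year, birth)) == group


def test_dialect_yaml_round_trip(tmp_path):
    path = tmp_path / "dialect.yaml"
    path.write_text(
        "name: CUSTOM\ncohort_bins:\n  - [1900, 1918]\n  - [1919, 1923]\n"
    )
    d = SurveyDialect.from_yaml(path)
    assert d.name == "CUSTOM"
    assert bin_cohort(1918, d) == "1900-1918"


def test_overlapping_bins_rejected():
    with pytest.raises(ValueError):
        SurveyDialect("BAD", ((1900, 1910), (1910, 1920)))


# ---------------------------------------------------------------------------
# panel reading & validation
# ---------------------------------------------------------------------------

HEADER = (
    "person_id,country,birth_year,gender,education_years,wave,interview_year,"
    "proxy,word_recall,serial7,orientation,adl_count,iadl_count,informant_score"
)


def _write(tmp_path, rows):
    path = tmp_path / "panel.csv"
    path.write_text("\n".join([HEADER, *rows]) + "\n")
    return path


GOOD_SELF = "P1,US,1920,female,12,1,2000,0,10,3,4,0,1,NA"
GOOD_PROXY = "P2,US,1915,male,8,1,2000,1,NA,NA,NA,3,4,4.2"


def test_read_panel_empty_data_section(tmp_path):
    records, report = read_panel(_write(tmp_path, []), HRS)
    assert len(records) == 0
    assert len(report) == 0


def test_read_panel_rejects_informant_score_on_self_respondent(tmp_path):
    bad = "P3,US,1920,female,12,1,2000,0,10,3,4,0,1,3.5"
    records, report = read_panel(_write(tmp_path, [GOOD_SELF, bad]), HRS)
    assert len(records) == 1
    assert len(report) == 1
    row, reason = report.rejections[0]
    assert row == 2
    assert "informant score on self-respondent" in reason


def test_read_panel_known_defect_fixture(tmp_path):
    """10 rows, 2 deliberately malformed → 8 records and 2 rejections."""
    rows = [GOOD_SELF, GOOD_PROXY] + [
        f"P{i},US,19{10 + i},male,10,1,2000,0,{i},2,3,1,1,NA" for i in range(4, 10)
    ]
    rows.append("P90,US,2005,male,10,1,2000,0,5,2,3,1,1,NA")  # interview before birth
    rows.append("P91,US,1920,male,10,1,2000,1,NA,NA,NA,1,1,NA")  # proxy, no informant
    records, report = read_panel(_write(tmp_path, rows), "HRS")
    assert len(records) == 8
    assert len(report) == 2
    assert {r for r, _ in report.rejections} == {9, 10}


def test_read_panel_mostly_bad_file_is_hard_error(tmp_path):
    rows = [GOOD_SELF] + ["P9,US,2005,male,10,1,2000,0,5,2,3,1,1,NA"] * 3
    with pytest.raises(PanelValidationError):
        read_panel(_write(tmp_path, rows), HRS)


def test_read_panel_unknown_dialect(tmp_path):
    with pytest.raises(PanelValidationError):
        read_panel(_write(tmp_path, [GOOD_SELF]), "NHANES")


def test_read_panel_missing_column(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("person_id,country\nP1,US\n")
    with pytest.raises(PanelValidationError):
        read_panel(path, HRS)


def test_panel_write_read_round_trip(tmp_path, small_observed):
    path = tmp_path / "roundtrip.csv"
    write_panel(small_observed, path)
    records, report = read_panel(path, HRS)
    assert len(report) == 0
    assert len(records) == len(small_observed)
    pd.testing.assert_series_equal(
        records["word_recall"], small_observed["word_recall"], check_names=True
    )


# ---------------------------------------------------------------------------
# GDP joins
# ---------------------------------------------------------------------------


def _gdp(rows):
    return GDPSeries(pd.DataFrame(rows, columns=["country", "year", "growth_pct"]))


def test_attach_gdp_constant_series():
    records = pd.DataFrame(
        {
            "person_id": ["A", "B"],
            "country": ["US", "US"],
            "interview_year": [2000, 2002],
        }
    )
    gdp = _gdp([("US", 2000, 2.0), ("US", 2002, 2.0)])
    out = attach_gdp(records, gdp)
    assert (out["gdp_growth"] == 2.0).all()


def test_attach_gdp_matches_each_country_row_by_row():
    records = pd.DataFrame(
        {
            "person_id": list("ABCDEF"),
            "country": ["US", "DE", "US", "DE", "US", "DE"],
            "interview_year": [2000, 2000, 2002, 2002, 2004, 2004],
        }
    )
    gdp = _gdp(
        [
            ("US", 2000, 1.0),
            ("US", 2002, 2.0),
            ("US", 2004, 3.0),
            ("DE", 2000, -1.0),
            ("DE", 2002, -2.0),
            ("DE", 2004, -3.0),
        ]
    )
    out = attach_gdp(records, gdp)
    expected = [1.0, -1.0, 2.0, -2.0, 3.0, -3.0]
    assert out["gdp_growth"].tolist() == expected


def test_attach_gdp_missing_coverage_names_pair():
    records = pd.DataFrame(
        {"person_id": ["A"], "country": ["FR"], "interview_year": [1999]}
    )
    gdp = _gdp([("US", 1999, 2.0)])
    with pytest.raises(CoverageError, match="FR"):
        attach_gdp(records, gdp)


def test_gdp_series_duplicate_entries_rejected():
    with pytest.raises(ValueError):
        _gdp([("US", 2000, 1.0), ("US", 2000, 2.0)])


def test_gdp_csv_round_trip(tmp_path, default_gdp):
    path = tmp_path / "gdp.csv"
    default_gdp.to_csv(path)
    back = GDPSeries.from_csv(path)
    pd.testing.assert_frame_equal(back.frame, default_gdp.frame)


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------


def _mini_panel(birth_years, interview_year=2000):
    return pd.DataFrame(
        {
            "person_id": [f"P{i}" for i in range(len(birth_years))],
            "country": "US",
            "birth_year": birth_years,
            "gender": "female",
            "education_years": 12,
            "wave": 1,
            "interview_year": interview_year,
            "proxy": False,
        }
    )


def test_filter_eligible_drops_young_respondents():
    # 3 of 10 aged 70 or younger in 2000
    births = [1929] * 7 + [1930, 1940, 1950]
    out = filter_eligible(_mini_panel(births), HRS)
    assert len(out) == 7
    assert (out["age"] >= 71).all()


def test_filter_eligible_is_identity_on_eligible_records():
    births = [1920, 1925, 1929]
    out = filter_eligible(_mini_panel(births), HRS)
    assert len(out) == 3
    assert out["cohort"].tolist() == ["1919-1923", "1924-1928", "1929-1933"]


def test_filter_eligible_empty_input():
    out = filter_eligible(_mini_panel([]), HRS)
    assert out.empty


def test_filter_eligible_drops_out_of_cohort_birth_years():
    out = filter_eligible(_mini_panel([1880, 1920]), HRS)  # 1880 pre-dates all bins
    assert out["birth_year"].tolist() == [1920]
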