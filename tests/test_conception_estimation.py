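"""Date arithmetic, conception-age classification, allocation and totals."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gestima.conception_estimation import (
    Classification,
    EstimateInterval,
    ScenarioBounds,
    abortion_scenario_counts,
    age_completed_years_365,
    allocate_fetal_deaths,
    classify_live_births_14,
    conception_date,
    estimated_total,
    gestation_days,
    registered_total,
    round_half_up,
)


@pytest.mark.parametrize("weeks,days", [(40, 280), (0, 0), (21, 147), (6, 42)])
def test_gestation_days_definition(weeks, days):
    assert gestation_days(weeks) == days


def test_gestation_days_rejects_negative():
    with pytest.raises(ValueError):
        gestation_days(-1)


def test_conception_date_examples():
    assert conception_date(date(2015, 9, 15), 40) == date(2014, 12, 9)
    d = date(2020, 2, 29)
    assert conception_date(d, 0) == d


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    st.dates(min_value=date(1990, 1, 1), max_value=date(2100, 1, 1)),
    st.integers(min_value=0, max_value=45),
)
def test_conception_date_inverts_gestation(outcome, weeks):
    """Adding the gestation back always recovers the outcome date."""
    assert conception_date(outcome, weeks) + timedelta(days=7 * weeks) == outcome


@pytest.mark.parametrize("days,years", [(5113, 14), (364, 0), (4745, 13), (365, 1)])
def test_age_completed_years_365(days, years):
    birth = date(2000, 1, 1)
    assert age_completed_years_365(birth + timedelta(days=days), birth) == years


def test_age_rejects_reference_before_birth():
    with pytest.raises(ValueError):
        age_completed_years_365(date(1999, 12, 31), date(2000, 1, 1))


def test_age_vectorised_with_missing_birth_dates():
    ref = pd.Series(pd.to_datetime(["2014-01-01", "2014-01-01"]))
    birth = pd.Series(pd.to_datetime(["2000-01-01", pd.NaT]))
    ages = age_completed_years_365(ref, birth)
    assert ages.iloc[0] == 14
    assert pd.isna(ages.iloc[1])


# ---------------------------------------------------------------------------
# classification and allocation


def _live_births(rows):
    return pd.DataFrame(
        rows,
        columns=["record_id", "mother_birth_date", "infant_birth_date", "gestational_weeks", "mother_age_recorded"],
    ).assign(
        mother_birth_date=lambda d: pd.to_datetime(d["mother_birth_date"]),
        infant_birth_date=lambda d: pd.to_datetime(d["infant_birth_date"]),
        gestational_weeks=lambda d: d["gestational_weeks"].astype("Int64"),
        mother_age_recorded=lambda d: d["mother_age_recorded"].astype("Int64"),
    )


def test_classification_partitions_and_reports_proportion():
    birth = pd.Timestamp("2000-01-01")
    # delivery at offset days since mother's birth; 40 weeks = 280 days
    conceived_13 = birth + pd.Timedelta(days=14 * 365 + 100)  # conception at 13
    conceived_14 = birth + pd.Timedelta(days=14 * 365 + 300)  # conception at 14
    df = _live_births(
        [
            ("a", birth, conceived_13, 40, 14),
            ("b", birth, conceived_14, 40, 14),
            ("c", birth, conceived_14, 0, 14),
        ]
    )
    result = classify_live_births_14(df)
    assert result.n_conceived_13 == 1
    assert result.n_conceived_14 == 2
    assert result.n_total == len(df)


def test_classification_empty_input_signals_undefined_proportion():
    with pytest.raises(ValueError, match="undefined"):
        classify_live_births_14(_live_births([]))


def test_all_conceived_at_14_gives_zero_proportion():
    birth = pd.Timestamp("2000-01-01")
    delivery = birth + pd.Timedelta(days=14 * 365 + 300)
    df = _live_births([("a", birth, delivery, 40, 14), ("b", birth, delivery, 40, 14)])
    assert classify_live_births_14(df).proportion == 0.0


def test_reference_proportion_prints_at_one_decimal():
    assert Classification(7127, 4290).proportion_pct == 62.4


@pytest.mark.parametrize(
    "n,p,expected",
    [(172, 7127 / 11417, 107), (0, 0.3, 0), (100, 0.5, 50), (3, 0.5, 2)],
)
def test_fetal_death_allocation_rounds_half_up_on_unrounded_p(n, p, expected):
    assert allocate_fetal_deaths(n, p) == expected


def test_allocation_rejects_bad_inputs():
    with pytest.raises(ValueError):
        allocate_fetal_deaths(-1, 0.5)
    with pytest.raises(ValueError):
        allocate_fetal_deaths(10, 1.5)


# ---------------------------------------------------------------------------
# abortion scenarios


def _abortions(rows):
    return pd.DataFrame(
        rows, columns=["record_id", "admission_date", "mother_birth_date", "mother_age_recorded"]
    ).assign(
        admission_date=lambda d: pd.to_datetime(d["admission_date"]),
        mother_birth_date=lambda d: pd.to_datetime(d["mother_birth_date"]),
        mother_age_recorded=lambda d: d["mother_age_recorded"].astype("Int64"),
    )


def test_abortion_scenario_border_case_counts_only_under_long_gestation():
    # 5,173 days old at admission: 6 weeks back -> 5,131 days -> age 14;
    # 21 weeks back -> 5,026 days -> age 13
    df = _abortions([("a", "2014-03-01", "2000-01-01", 14)])
    assert (pd.Timestamp("2014-03-01") - pd.Timestamp("2000-01-01")).days == 5173
    counts = abortion_scenario_counts(df, ScenarioBounds(6, 21))
    assert (counts.count_low, counts.count_high) == (0, 1)


def test_abortion_scenarios_empty_input():
    counts = abortion_scenario_counts(_abortions([]))
    assert (counts.count_low, counts.count_high) == (0, 0)


def test_abortion_missing_birth_dates_skipped_and_tallied():
    df = _abortions(
        [("a", "2014-03-01", "2000-01-01", 14), ("b", "2014-03-01", pd.NaT, 14)]
    )
    counts = abortion_scenario_counts(df)
    assert counts.n_missing_birth_date == 1
    assert counts.count_low + counts.count_high >= 0


def test_scenario_monotonicity_on_random_consistent_records():
    """Longer assumed gestation never reduces the conceived-at-13 count."""
    rng = np.random.default_rng(42)
    n = 2000
    admission = pd.Series(
        pd.Timestamp("2012-01-01") + pd.to_timedelta(rng.integers(0, 4018, n), unit="D")
    )
    # recorded-age-14-consistent offsets: [14*365, 14*365+364] days
    offsets = 14 * 365 + rng.integers(0, 365, n)
    df = pd.DataFrame(
        {
            "record_id": [f"r{i}" for i in range(n)],
            "admission_date": admission,
            "mother_birth_date": admission - pd.to_timedelta(offsets, unit="D"),
            "mother_age_recorded": pd.array([14] * n, dtype="Int64"),
        }
    )
    counts = abortion_scenario_counts(df, ScenarioBounds(6, 21))
    assert counts.count_high >= counts.count_low


def test_scenario_bounds_validation():
    with pytest.raises(ValueError):
        ScenarioBounds(21, 6)
    with pytest.raises(ValueError):
        ScenarioBounds(0, 21)


# ---------------------------------------------------------------------------
# totals


def test_registered_total_is_exact_commutative_sum():
    assert registered_total(4317, 64, 3, 455) == 4839
    assert registered_total(0, 0, 0, 0) == 0
    assert registered_total(455, 3, 64, 4317) == 4839  # order-independent


def test_estimated_total_interval_and_components():
    interval = estimated_total(4839, 7127, 107, 64, 281)
    assert (interval.min_count, interval.max_count) == (12137, 12354)
    assert interval.width == 281 - 64
    assert interval.components["registered"] == 4839


def test_estimated_total_zero_extras_degenerate_interval():
    interval = estimated_total(100, 0, 0, 0, 0)
    assert (interval.min_count, interval.max_count) == (100, 100)


def test_estimated_total_rejects_inverted_scenarios():
    with pytest.raises(ValueError):
        estimated_total(100, 0, 0, 5, 2)


def test_interval_invariants_enforced():
    with pytest.raises(ValueError):
        EstimateInterval(5, 2)


@pytest.mark.parametrize("x,nd,expected", [(0.5, 0, 1.0), (1.5, 0, 2.0), (107.37, 0, 107.0), (62.45, 1, 62.5), (2.508, 1, 2.5)])
def test_round_half_up(x, nd, expected):
    assert round_half_up(x, nd) == expected
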