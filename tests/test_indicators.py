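"""Fertility rates, notification coverage, perinatal indicators and ratios."""

import numpy as np
import pandas as pd
import pytest

from gestima.indicators import (
    comparison_ratios,
    fertility_rate,
    notification_coverage,
    perinatal_indicators,
    perinatal_indicators_from_counts,
    select_rape_notifications,
)
from gestima.schema_io import StudyPeriod


@pytest.mark.parametrize(
    "pregnancies,population,n_years,expected",
    [(4839, 2851664, 11, 1.70), (12354, 2851664, 11, 4.33), (0, 1000, 5, 0.0)],
)
def test_fertility_rate_examples(pregnancies, population, n_years, expected):
    assert fertility_rate(pregnancies, population, n_years) == expected


def test_fertility_rate_invariant_to_n_years():
    """Annual means cancel: the rate depends only on the period totals."""
    rng = np.random.default_rng(0)
    for _ in range(50):
        preg = int(rng.integers(0, 10000))
        pop = int(rng.integers(1, 10**7))
        assert fertility_rate(preg, pop, 1) == fertility_rate(preg, pop, 11)


def test_fertility_rate_zero_population_is_an_error():
    with pytest.raises(ValueError):
        fertility_rate(10, 0, 1)


@pytest.mark.parametrize(
    "notifications,pregnancies,expected",
    [(1410, 4839, 29.1), (1410, 12354, 11.4), (1410, 12137, 11.6), (5, 4, 125.0)],
)
def test_notification_coverage_examples(notifications, pregnancies, expected):
    assert notification_coverage(notifications, pregnancies) == expected


def test_coverage_zero_pregnancies_signalled():
    with pytest.raises(ValueError, match="undefined"):
        notification_coverage(10, 0)


def test_coverage_decreases_with_larger_denominator():
    rng = np.random.default_rng(1)
    for _ in range(50):
        n = int(rng.integers(0, 500))
        reg = int(rng.integers(1, 5000))
        est = reg + int(rng.integers(0, 5000))
        assert notification_coverage(n, est) <= notification_coverage(n, reg)


# ---------------------------------------------------------------------------
# notification selection


def _notifications(rows):
    df = pd.DataFrame(
        rows,
        columns=["record_id", "victim_sex", "victim_age", "occurrence_date", "rape_flag", "region_id"],
    )
    df["occurrence_date"] = pd.to_datetime(df["occurrence_date"])
    df["victim_age"] = df["victim_age"].astype("Int64")
    df["rape_flag"] = df["rape_flag"].astype("boolean")
    return df


def test_select_applies_all_four_filters():
    period = StudyPeriod(2012, 2022)
    df = _notifications(
        [
            ("keep", "female", 12, "2015-05-01", True, "R01"),
            ("too_old", "female", 14, "2015-05-01", True, "R01"),
            ("male", "male", 12, "2015-05-01", True, "R01"),
            ("no_flag", "female", 12, "2015-05-01", False, "R01"),
            ("early", "female", 12, "2011-12-31", True, "R01"),
            ("keep2", "female", 10, "2022-12-31", True, "R02"),
        ]
    )
    assert select_rape_notifications(df, period) == 2
    by_region = select_rape_notifications(df, period, by_region=True)
    assert by_region.to_dict() == {"R01": 1, "R02": 1}


def test_selected_count_matches_generator_truth(clean_cohort):
    """Without distractors the selection equals the ground-truth tally."""
    period = StudyPeriod(
        clean_cohort.config.first_year, clean_cohort.config.last_year
    )
    gt = clean_cohort.ground_truth
    expected = int(
        (
            gt["truly_notified"]
            & gt["true_age_at_conception"].between(10, 13)
            & gt["true_conception_date"].dt.year.between(
                period.first_year, period.last_year
            )
        ).sum()
    )
    measured = select_rape_notifications(clean_cohort.violence_notifications, period)
    assert measured == expected


def test_measured_coverage_tracks_true_coverage(clean_cohort):
    """Measured coverage ~= c x (conception-qualifying / registered) +- 3 SE."""
    cfg = clean_cohort.config
    period = StudyPeriod(cfg.first_year, cfg.last_year)
    gt = clean_cohort.ground_truth
    qualifying = int(
        (
            gt["true_age_at_conception"].between(10, 13)
            & gt["true_conception_date"].dt.year.between(
                period.first_year, period.last_year
            )
        ).sum()
    )
    registered = int((gt["true_age_at_outcome"].between(10, 13)).sum())
    c = cfg.notification_coverage_true
    measured_notifications = select_rape_notifications(
        clean_cohort.violence_notifications, period
    )
    se = np.sqrt(qualifying * c * (1 - c))
    assert abs(measured_notifications - c * qualifying) <= 3 * se
    measured_cov = notification_coverage(measured_notifications, registered)
    expected_cov = 100.0 * c * qualifying / registered
    assert abs(measured_cov - expected_cov) <= 100.0 * 3 * se / registered


# ---------------------------------------------------------------------------
# perinatal indicators and ratios


def test_fetal_mortality_uses_total_births_denominator():
    row = perinatal_indicators_from_counts(
        n_live_births=1000,
        n_preterm=0,
        n_low_birth_weight=0,
        n_fetal_deaths=10,
        n_neonatal_deaths=0,
        n_maternal_deaths=0,
        n_legal_abortions=0,
        n_notifications=0,
    )
    assert row["fetal_mortality_per_1000"] == 9.90  # 10 / 1010 x 1000


def test_all_zero_numerators_give_zero_rates():
    row = perinatal_indicators_from_counts(100, 0, 0, 0, 0, 0, 0, 10)
    for key in ("preterm_pct", "lbw_pct", "fetal_mortality_per_1000",
                "neonatal_mortality_per_1000", "mmr_per_100000",
                "legal_abortion_to_notification_pct"):
        assert row[key] == 0.0


def test_zero_live_births_marks_cells_undefined():
    row = perinatal_indicators_from_counts(0, 0, 0, 5, 0, 0, 0, 0)
    assert row["preterm_pct"] is None
    assert row["lbw_pct"] is None
    assert row["neonatal_mortality_per_1000"] is None
    assert row["mmr_per_100000"] is None
    assert row["legal_abortion_to_notification_pct"] is None
    # fetal mortality still defined: denominator is fetal deaths + live births
    assert row["fetal_mortality_per_1000"] == 1000.0


def test_perinatal_indicators_from_record_frames():
    lb = pd.DataFrame(
        {
            "gestational_weeks": pd.array([36, 39, 40, pd.NA], dtype="Int64"),
            "infant_birth_weight_g": pd.array([2400, 3200, 2600, 3100], dtype="Int64"),
        }
    )
    empty = pd.DataFrame(
        {"record_id": [], "icd10_code": pd.Series([], dtype=object)}
    )
    abortions = pd.DataFrame({"icd10_code": ["O04", "O03", "O041"]})
    row = perinatal_indicators(lb, empty, empty, empty, abortions, n_notifications=10)
    assert row["preterm_pct"] == 25.0  # 1 of 4 live births
    assert row["lbw_pct"] == 25.0
    assert row["n_legal_abortions"] == 2  # O04 and O04.1
    assert row["legal_abortion_to_notification_pct"] == 20.0


def test_comparison_ratio_examples():
    young = {"fetal_mortality_per_1000": 14.6, "mmr_per_100000": 301.1}
    adult = {"fetal_mortality_per_1000": 11.4, "mmr_per_100000": 69.8}
    ratios = comparison_ratios(young, adult, indicators=tuple(young))
    assert ratios["fetal_mortality_per_1000"] == 1.28
    # from printed (rounded) cells; unrounded microdata prints 4.32
    assert ratios["mmr_per_100000"] == 4.31


def test_identical_rows_give_unit_ratios():
    row = {"preterm_pct": 18.5, "lbw_pct": 14.2}
    ratios = comparison_ratios(row, row, indicators=tuple(row))
    assert set(ratios.values()) == {1.00}


def test_zero_adult_value_is_an_error():
    with pytest.raises(ValueError, match="zero adult"):
        comparison_ratios(
            {"preterm_pct": 1.0}, {"preterm_pct": 0.0}, indicators=("preterm_pct",)
        )


def test_undefined_cell_is_an_error():
    with pytest.raises(ValueError, match="undefined"):
        comparison_ratios(
            {"preterm_pct": None}, {"preterm_pct": 2.0}, indicators=("preterm_pct",)
        )
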