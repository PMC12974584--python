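"""Fertility rates, notification coverage and perinatal outcome indicators.

Definitions
-----------
specific fertility rate (per 1,000)
    mean annual pregnancies divided by mean annual female population of the
    age group; with a common period the annual means cancel, so the rate
    equals total pregnancies / total person-years x 1,000.
notification coverage (%)
    rape notifications for girls 10-13 divided by pregnancies in the same
    stratum.  Pregnancies are a *proxy* denominator (not every rape results
    in pregnancy), so true notification coverage is lower than reported
    here; the value is never clamped and may exceed 100% where referral
    services concentrate cases from other regions.
perinatal indicators
    low birth weight (< 2,500 g) and preterm (< 37 weeks) as percentages of
    live births; fetal mortality per 1,000 total births (fetal deaths +
    live births); neonatal mortality (deaths at 0-27 days) per 1,000 live
    births; maternal mortality ratio per 100,000 live births; and legal
    abortions (ICD-10 O04) per 100 rape notifications.

Reported rounding matches conventional surveillance precision: rates per
1,000 to 2 decimals, percentages and the MMR to 1 decimal, comparison
ratios to 2 decimals.  Indicators with a zero denominator are returned as
``None`` (signalled per cell, never silently zero); every rate is reported
alongside its numerator and denominator.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .conception_estimation import round_half_up
from .schema_io import StudyPeriod, icd10_category

__all__ = [
    "INDICATOR_COLUMNS",
    "comparison_ratios",
    "fertility_rate",
    "notification_coverage",
    "perinatal_indicators",
    "perinatal_indicators_from_counts",
    "select_rape_notifications",
]

#: Column order of an indicator table row (one row per region|state x period
#: x age group).  ``pregnancies_estimated_min/max`` are populated only where
#: the age-14 extras can be estimated (state level).
INDICATOR_COLUMNS = [
    "pregnancies_registered",
    "pregnancies_estimated_min",
    "pregnancies_estimated_max",
    "fertility_rate_per_1000",
    "notifications",
    "coverage_pct",
    "preterm_pct",
    "lbw_pct",
    "fetal_mortality_per_1000",
    "neonatal_mortality_per_1000",
    "mmr_per_100000",
    "legal_abortion_to_notification_pct",
]


def fertility_rate(
    pregnancies_period_total: int, population_period_total: int, n_years: int = 1
) -> float:
    """Specific fertility rate per 1,000, rounded to 2 decimals.

    ``(pregnancies/n_years) / (population/n_years) x 1000`` — algebraically
    the annual means cancel, so the result is invariant to ``n_years``; the
    parameter is kept for interface clarity with per-period totals.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if population_period_total <= 0:
        raise ValueError("fertility rate undefined for zero population")
    mean_pregnancies = pregnancies_period_total / n_years
    mean_population = population_period_total / n_years
    return round_half_up(mean_pregnancies / mean_population * 1000.0, 2)


def notification_coverage(notifications: int, pregnancies: int) -> float:
    """Rape-notification coverage as a percentage at one decimal, not clamped.

    Raises
    ------
    ValueError
        Zero pregnancies in the denominator (undefined, signalled).
    """
    if pregnancies <= 0:
        raise ValueError("coverage undefined for zero pregnancies")
    return round_half_up(notifications / pregnancies * 100.0, 1)


def select_rape_notifications(
    notifications: pd.DataFrame,
    period: StudyPeriod,
    by_region: bool = False,
):
    """Count qualifying rape notifications: female victims aged 10-13.

    A notification qualifies when all four filters pass: female victim,
    rape flag set, victim age in [10, 13], and the aggression's occurrence
    year inside the period.  Returns an integer, or a per-region Series
    (indexed by ``region_id``) when ``by_region`` is set.
    """
    sex = notifications["victim_sex"].astype("string").str.lower()
    mask = (
        (sex == "female")
        & notifications["rape_flag"].fillna(False).astype(bool)
        & notifications["victim_age"].between(10, 13).fillna(False)
        & period.contains_year(notifications["occurrence_date"].dt.year).fillna(False)
    )
    if by_region:
        return notifications.loc[mask].groupby("region_id").size()
    return int(mask.sum())


def perinatal_indicators_from_counts(
    n_live_births: int,
    n_preterm: int,
    n_low_birth_weight: int,
    n_fetal_deaths: int,
    n_neonatal_deaths: int,
    n_maternal_deaths: int,
    n_legal_abortions: int,
    n_notifications: int,
) -> dict[str, float | int | None]:
    """Perinatal indicator row from stratum counts; ``None`` marks undefined cells."""

    def ratio(num, den, scale, ndigits):
        if den <= 0:
            return None
        return round_half_up(num / den * scale, ndigits)

    nv = n_live_births
    return {
        "preterm_pct": ratio(n_preterm, nv, 100.0, 1),
        "lbw_pct": ratio(n_low_birth_weight, nv, 100.0, 1),
        "fetal_mortality_per_1000": ratio(n_fetal_deaths, n_fetal_deaths + nv, 1000.0, 2),
        "neonatal_mortality_per_1000": ratio(n_neonatal_deaths, nv, 1000.0, 2),
        "mmr_per_100000": ratio(n_maternal_deaths, nv, 100000.0, 1),
        "legal_abortion_to_notification_pct": ratio(
            n_legal_abortions, n_notifications, 100.0, 1
        ),
        "n_live_births": nv,
        "n_preterm": n_preterm,
        "n_low_birth_weight": n_low_birth_weight,
        "n_fetal_deaths": n_fetal_deaths,
        "n_neonatal_deaths": n_neonatal_deaths,
        "n_maternal_deaths": n_maternal_deaths,
        "n_legal_abortions": n_legal_abortions,
        "n_notifications": n_notifications,
    }


def perinatal_indicators(
    live_births: pd.DataFrame,
    fetal_deaths: pd.DataFrame,
    neonatal_deaths: pd.DataFrame,
    maternal_deaths: pd.DataFrame,
    abortion_admissions: pd.DataFrame,
    n_notifications: int,
) -> dict[str, float | int | None]:
    """Perinatal indicator row computed from one stratum's record collections.

    Preterm and low-birth-weight counts use records with a known value;
    denominators are total live births in the stratum.  Maternal deaths are
    counted regardless of timing relative to the end of pregnancy (the MMR
    is deaths per live birth, not a pregnancy tally).
    """
    weeks = live_births["gestational_weeks"]
    weight = live_births["infant_birth_weight_g"]
    legal = (
        abortion_admissions["icd10_code"].map(icd10_category) == "O04"
        if len(abortion_admissions)
        else pd.Series(dtype=bool)
    )
    return perinatal_indicators_from_counts(
        n_live_births=len(live_births),
        n_preterm=int((weeks < 37).sum()),
        n_low_birth_weight=int((weight < 2500).sum()),
        n_fetal_deaths=len(fetal_deaths),
        n_neonatal_deaths=len(neonatal_deaths),
        n_maternal_deaths=len(maternal_deaths),
        n_legal_abortions=int(legal.sum()),
        n_notifications=int(n_notifications),
    )


def comparison_ratios(
    row_young: Mapping[str, float | None],
    row_adult: Mapping[str, float | None],
    indicators: tuple[str, ...] = (
        "preterm_pct",
        "lbw_pct",
        "fetal_mortality_per_1000",
        "neonatal_mortality_per_1000",
        "mmr_per_100000",
        "legal_abortion_to_notification_pct",
    ),
) -> dict[str, float]:
    """Elementwise young/adult indicator ratios at two decimals.

    Both rows must have defined (non-``None``) values for every compared
    indicator; a zero adult value is an error.  Ratios of values that were
    themselves rounded for printing can differ in the last digit from ratios
    of the unrounded microdata (about +-0.01).
    """
    out: dict[str, float] = {}
    for key in indicators:
        y, a = row_young.get(key), row_adult.get(key)
        if y is None or a is None:
            raise ValueError(f"indicator {key!r} undefined in one of the rows")
        if a == 0:
            raise ValueError(f"zero adult value for {key!r}")
        out[key] = round_half_up(y / a, 2)
    return out
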