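"""Conception-date arithmetic and the bounded pregnancy-count estimator.

The core method: for a pregnancy whose outcome (delivery, fetal demise or
abortion admission) was recorded at maternal age 14, impute the mother's age
at conception and decide whether the pregnancy belongs with the 10-13 age
group.  The arithmetic is deliberately simple and is applied everywhere with
one shared convention:

    gestation days   = gestational weeks x 7
    conception date  = outcome date - gestation days
    age (completed years) = floor((date - mother's birth date) / 365 days)

The 365-day completed-years convention — **not** calendar birthdays, and with
no leap-day correction — governs all age logic in the package, both here and
in the eligibility filter, so the two stages can never disagree on an age.

Live births carry a recorded gestational age, so each record is classified
individually.  Fetal-death certificates lack the mother's birth date, so the
conceived-at-13 proportion observed among live births is allocated
proportionally.  Abortion admissions lack a gestational age, so the count is
bounded by two scenarios: a short gestation (default 6 weeks, the earliest a
gestational sac is sonographically detectable) and a long one (default 21
weeks, the upper limit for classifying the outcome as an early fetal loss).
Maternal deaths before the end of pregnancy enter the registered total only;
with neither gestational age nor a usable outcome date for the fetus, no
age-14 extra can be estimated for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import timedelta
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import pandas as pd

__all__ = [
    "DAYS_PER_YEAR",
    "Classification",
    "EstimateInterval",
    "ScenarioBounds",
    "ScenarioCounts",
    "add_conception_columns",
    "age_completed_years_365",
    "allocate_fetal_deaths",
    "abortion_scenario_counts",
    "classify_live_births_14",
    "conception_date",
    "estimated_total",
    "gestation_days",
    "registered_total",
    "round_half_up",
]

DAYS_PER_YEAR = 365  # completed-years divisor; fixed by the method, not configurable
DAYS_PER_WEEK = 7


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (``0.5 -> 1``), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    v = float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
    return v


def gestation_days(weeks):
    """Convert gestational weeks to days: exactly ``7 x weeks``.

    Accepts an integer or an integer Series (missing allowed, propagated).
    """
    if isinstance(weeks, pd.Series):
        if (weeks.dropna() < 0).any():
            raise ValueError("negative gestational weeks")
        return weeks * DAYS_PER_WEEK
    if weeks < 0:
        raise ValueError(f"negative gestational weeks: {weeks}")
    return int(weeks) * DAYS_PER_WEEK


def conception_date(outcome_date, weeks):
    """Calendar date of conception: outcome date minus ``7 x weeks`` days.

    Works on a single :class:`datetime.date` (or Timestamp) with integer
    weeks, or vectorised on datetime/integer Series.
    """
    days = gestation_days(weeks)
    if isinstance(outcome_date, pd.Series):
        if isinstance(days, pd.Series):
            days = days.astype("Float64").astype(float)  # NA -> NaN -> NaT
        return outcome_date - pd.to_timedelta(days, unit="D")
    return outcome_date - timedelta(days=int(days))


def age_completed_years_365(reference_date, birth_date):
    """Age in completed years under the 365-day convention.

    ``floor((reference_date - birth_date) / 365 days)``, no leap-day
    correction.  Vectorised on datetime Series (missing birth dates yield
    missing ages).

    Raises
    ------
    ValueError
        If any reference date precedes the birth date.
    """
    if isinstance(reference_date, pd.Series) or isinstance(birth_date, pd.Series):
        days = (pd.Series(reference_date) - pd.Series(birth_date)).dt.days
        if (days.dropna() < 0).any():
            raise ValueError("reference date precedes birth date")
        return pd.Series(days // DAYS_PER_YEAR).astype("Int64")
    days = (reference_date - birth_date).days
    if days < 0:
        raise ValueError(
            f"reference date {reference_date} precedes birth date {birth_date}"
        )
    return days // DAYS_PER_YEAR


def add_conception_columns(
    records: pd.DataFrame,
    outcome_col: str,
    weeks_col: str = "gestational_weeks",
    birth_col: str = "mother_birth_date",
    assumed_weeks: int | None = None,
) -> pd.DataFrame:
    """Annotate records with gestation_days, conception_date and age_at_conception.

    ``assumed_weeks`` substitutes a fixed gestational age for every record
    (the abortion scenarios); otherwise ``weeks_col`` is used row-wise.
    """
    out = records.copy()
    weeks = assumed_weeks if assumed_weeks is not None else out[weeks_col]
    out["gestation_days"] = gestation_days(weeks)
    out["conception_date"] = conception_date(out[outcome_col], weeks)
    out["age_at_conception"] = age_completed_years_365(
        out["conception_date"], out[birth_col]
    )
    return out


# ---------------------------------------------------------------------------
# classification of age-14 live births


@dataclass(frozen=True)
class Classification:
    """Split of eligible age-14 deliveries by imputed age at conception."""

    n_conceived_13: int
    n_conceived_14: int

    @property
    def n_total(self) -> int:
        return self.n_conceived_13 + self.n_conceived_14

    @property
    def proportion(self) -> float:
        """Unrounded conceived-at-13 fraction; feeds the fetal-death allocation."""
        if self.n_total == 0:
            raise ValueError("proportion undefined: no eligible records")
        return self.n_conceived_13 / self.n_total

    @property
    def proportion_pct(self) -> float:
        """The fraction as a percentage at one decimal, for reporting."""
        return round_half_up(100.0 * self.proportion, 1)


def classify_live_births_14(eligible: pd.DataFrame) -> Classification:
    """Classify eligible age-14 live births by age at conception (13 vs 14).

    ``eligible`` must already have passed
    :func:`gestima.eligibility.filter_14yo_live_births`, which guarantees a
    present gestational age and birth date and a consistent recorded age —
    under those guarantees every imputed conception age is 13 or 14, so the
    classification partitions the input.

    Raises
    ------
    ValueError
        Empty input (the proportion would be undefined), or records whose
        conception age falls outside {13, 14} (a violated precondition).
    """
    if len(eligible) == 0:
        raise ValueError("proportion undefined: no eligible age-14 live births")
    ann = add_conception_columns(eligible, outcome_col="infant_birth_date")
    ages = ann["age_at_conception"]
    n13 = int((ages == 13).sum())
    n14 = int((ages == 14).sum())
    if n13 + n14 != len(eligible):
        stray = sorted(ages[~ages.isin([13, 14])].unique().tolist())
        raise ValueError(
            f"conception ages outside {{13, 14}} ({stray}); "
            "input was not pre-filtered to consistent age-14 records"
        )
    return Classification(n13, n14)


def allocate_fetal_deaths(n_14yo_fetal_deaths: int, proportion_p: float) -> int:
    """Allocate age-14 fetal deaths to conception-at-13 by the live-birth proportion.

    Fetal-death certificates carry no maternal birth date, so the
    conceived-at-13 proportion observed among live births is assumed to hold
    for fetal demises too.  Uses the *unrounded* proportion and rounds the
    product to the nearest integer (ties half-up).
    """
    if n_14yo_fetal_deaths < 0:
        raise ValueError("negative count")
    if not 0.0 <= proportion_p <= 1.0:
        raise ValueError(f"proportion {proportion_p} outside [0, 1]")
    return int(round_half_up(n_14yo_fetal_deaths * proportion_p))


# ---------------------------------------------------------------------------
# abortion scenarios


@dataclass(frozen=True)
class ScenarioBounds:
    """Assumed gestational ages bounding the abortion-admission imputation.

    Admission records carry no gestational age, so conception is imputed
    under a short-gestation scenario (``ga_low_weeks``) and a long-gestation
    one (``ga_high_weeks``); longer gestation places conception earlier,
    hence at a younger age, so the long scenario yields the larger count.
    """

    ga_low_weeks: int = 6
    ga_high_weeks: int = 21

    def __post_init__(self) -> None:
        if not 0 < self.ga_low_weeks < self.ga_high_weeks:
            raise ValueError(
                f"need 0 < ga_low_weeks < ga_high_weeks, got "
                f"({self.ga_low_weeks}, {self.ga_high_weeks})"
            )


@dataclass(frozen=True)
class ScenarioCounts:
    count_low: int
    count_high: int
    n_missing_birth_date: int = 0


def abortion_scenario_counts(
    records_14yo: pd.DataFrame, bounds: ScenarioBounds = ScenarioBounds()
) -> ScenarioCounts:
    """Bound the number of age-14 abortion admissions conceived at 13.

    The admission date stands in for the end-of-pregnancy date.  For each
    scenario gestational age, conception age is imputed for every record
    with a known maternal birth date; records missing it are skipped and
    tallied in the result.  Returns counts of records whose imputed
    conception age is 13 under the low and high scenarios.
    """
    usable = records_14yo[records_14yo["mother_birth_date"].notna()]
    skipped = len(records_14yo) - len(usable)

    def count_at(weeks: int) -> int:
        if len(usable) == 0:
            return 0
        ann = add_conception_columns(
            usable, outcome_col="admission_date", assumed_weeks=weeks
        )
        return int((ann["age_at_conception"] == 13).sum())

    return ScenarioCounts(
        count_low=count_at(bounds.ga_low_weeks),
        count_high=count_at(bounds.ga_high_weeks),
        n_missing_birth_date=skipped,
    )


# ---------------------------------------------------------------------------
# totals


def registered_total(
    nv: int, fetal: int, maternal_before_end: int, abortions: int
) -> int:
    """Registered pregnancies: the exact sum of the four outcome streams.

    Live births + fetal deaths + maternal deaths before the end of pregnancy
    + hospital abortion admissions, all at recorded maternal age 10-13.
    """
    parts = (nv, fetal, maternal_before_end, abortions)
    if any(p < 0 for p in parts):
        raise ValueError(f"negative component in {parts}")
    return int(sum(parts))


@dataclass(frozen=True)
class EstimateInterval:
    """Interval estimate of pregnancies at ages 10-13, with provenance.

    ``components`` records every named integer contribution (registered
    total, age-14 extras from live births and fetal deaths, and the two
    abortion scenario counts), so the totals can always be audited.
    """

    min_count: int
    max_count: int
    components: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_count > self.max_count:
            raise ValueError(f"min {self.min_count} > max {self.max_count}")
        reg = self.components.get("registered")
        if reg is not None and self.min_count < reg:
            raise ValueError("interval below the registered component")

    @property
    def width(self) -> int:
        return self.max_count - self.min_count


def estimated_total(
    registered: int,
    extra_live_births: int,
    extra_fetal_deaths: int,
    extra_abortions_low: int,
    extra_abortions_high: int,
) -> EstimateInterval:
    """Combine registered cases and age-14 extras into the interval estimate.

    min = registered + live-birth extras + fetal-death extras + low abortion
    scenario; max uses the high scenario.  Maternal deaths contribute to the
    registered component only — no extra can be estimated for them.
    """
    parts = (
        registered,
        extra_live_births,
        extra_fetal_deaths,
        extra_abortions_low,
        extra_abortions_high,
    )
    if any(p < 0 for p in parts):
        raise ValueError(f"negative component in {parts}")
    if extra_abortions_low > extra_abortions_high:
        raise ValueError(
            f"abortion scenario low {extra_abortions_low} > high {extra_abortions_high}"
        )
    base = registered + extra_live_births + extra_fetal_deaths
    return EstimateInterval(
        min_count=base + extra_abortions_low,
        max_count=base + extra_abortions_high,
        components={
            "registered": registered,
            "extra_live_births": extra_live_births,
            "extra_fetal_deaths": extra_fetal_deaths,
            "extra_abortions_min": extra_abortions_low,
            "extra_abortions_max": extra_abortions_high,
        },
    )
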