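"""Record-exclusion rules applied before conception-age estimation.

Live-birth certificates of mothers recorded as 14 years old can only be
classified by age at conception when three fields are usable: the
gestational age, the mother's birth date, and a recorded age consistent with
the age recomputed from the dates.  A record failing any of the three is
excluded (it may carry several reasons; it is excluded once).

The age-consistency check uses the same 365-day completed-years function as
the estimator — a single shared implementation, so the filter and the
classifier can never apply divergent conventions — and requires exact
equality, with no one-year tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .conception_estimation import age_completed_years_365

__all__ = ["EXCLUSION_REASONS", "ExclusionReport", "exclusion_flags", "filter_14yo_live_births"]

EXCLUSION_REASONS = (
    "missing_gestational_age",
    "missing_mother_birth_date",
    "age_inconsistent",
)


@dataclass(frozen=True)
class ExclusionReport:
    """Tally of the eligibility filter.

    ``eligible_count + excluded_count == input_count`` always; the per-reason
    counts may sum to more than ``excluded_count`` because a record can fail
    several rules at once (reasons are tallied independently, not
    hierarchically).
    """

    input_count: int
    eligible_count: int
    excluded_count: int
    missing_gestational_age: int
    missing_mother_birth_date: int
    age_inconsistent: int

    def __post_init__(self) -> None:
        if self.eligible_count + self.excluded_count != self.input_count:
            raise ValueError("eligible + excluded must equal input")

    def to_dict(self) -> dict[str, int]:
        return {
            "input_count": self.input_count,
            "eligible_count": self.eligible_count,
            "excluded_count": self.excluded_count,
            "missing_gestational_age": self.missing_gestational_age,
            "missing_mother_birth_date": self.missing_mother_birth_date,
            "age_inconsistent": self.age_inconsistent,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])


def exclusion_flags(records: pd.DataFrame) -> pd.DataFrame:
    """Per-record boolean flags for the three exclusion reasons.

    Age consistency is evaluated only where the mother's birth date is
    present (a missing date is its own reason); a missing recorded age with
    a present birth date counts as inconsistent, since the recorded age
    cannot be confirmed.
    """
    m_ga = records["gestational_weeks"].isna()
    m_dob = records["mother_birth_date"].isna()
    computed = age_completed_years_365(
        records["infant_birth_date"], records["mother_birth_date"]
    )
    mismatch = computed.ne(records["mother_age_recorded"]).fillna(True)
    inconsistent = (~m_dob) & mismatch
    return pd.DataFrame(
        {
            "missing_gestational_age": m_ga.astype(bool),
            "missing_mother_birth_date": m_dob.astype(bool),
            "age_inconsistent": inconsistent.astype(bool),
        },
        index=records.index,
    )


def filter_14yo_live_births(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Partition age-14 live-birth records into eligible and excluded.

    ``records`` must be pre-restricted to recorded mother age 14 at
    delivery.  A record is excluded iff its gestational age is missing, the
    mother's birth date is missing, or the age recomputed from the dates
    (365-day convention) differs from the recorded age.  The filter is
    idempotent: re-filtering the eligible set excludes nothing.

    Returns the eligible records (index reset) and an :class:`ExclusionReport`.
    """
    flags = exclusion_flags(records)
    excluded = flags.any(axis=1)
    eligible = records.loc[~excluded].reset_index(drop=True)
    report = ExclusionReport(
        input_count=len(records),
        eligible_count=int((~excluded).sum()),
        excluded_count=int(excluded.sum()),
        missing_gestational_age=int(flags["missing_gestational_age"].sum()),
        missing_mother_birth_date=int(flags["missing_mother_birth_date"].sum()),
        age_inconsistent=int(flags["age_inconsistent"].sum()),
    )
    return eligible, report
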