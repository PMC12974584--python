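"""Desk-scale reproduction of the published reference estimates.

The estimation method was applied to the vital-records systems of Maranhão,
Brazil, for 2012-2022; the published analysis prints the component counts of
that application (registered outcomes by stream, the age-14 live-birth
cohort and its exclusions, the age-14 fetal-death count, the two abortion
scenario counts, the notification total and the period population).  Those
printed components are *inputs*; every headline estimate follows from them
by the package's own arithmetic, so this module recomputes each one at run
time and compares it with the published value.  It is a regression harness
for the method's arithmetic, not a substitute for running the pipeline on
microdata.
"""

from __future__ import annotations

import pandas as pd

from .conception_estimation import (
    Classification,
    allocate_fetal_deaths,
    estimated_total,
    registered_total,
    round_half_up,
)
from .indicators import comparison_ratios, fertility_rate, notification_coverage

__all__ = [
    "PUBLISHED",
    "REFERENCE_INPUTS",
    "compute_reference_estimates",
    "verify_reference_arithmetic",
]

#: Printed component counts of the reference application (Maranhão 2012-2022).
REFERENCE_INPUTS: dict[str, float] = {
    # registered outcomes at recorded maternal age 10-13
    "live_births_10_13": 4317,
    "fetal_deaths_10_13": 64,
    "maternal_deaths_before_end_10_13": 3,
    "abortion_admissions_10_13": 455,
    # the age-14 live-birth cohort and its classification
    "live_births_14_total": 12754,
    "live_births_14_excluded": 1337,
    "conceived_at_13": 7127,
    "conceived_at_14": 4290,
    # age-14 extras in the other streams
    "fetal_deaths_14": 172,
    "abortion_extra_low": 64,
    "abortion_extra_high": 281,
    # notifications and population
    "rape_notifications_10_13": 1410,
    "population_10_13_period": 2851664,
    "n_years": 11,
    # printed fetal-mortality cells of the 10-13 vs 20-29 comparison
    "fetal_mortality_10_13_per_1000": 14.6,
    "fetal_mortality_20_29_per_1000": 11.4,
}

#: Published headline values the arithmetic must reproduce.
PUBLISHED: dict[str, float] = {
    "registered_pregnancies": 4839,
    "eligible_live_births_14": 11417,
    "conceived_at_13_pct": 62.4,
    "fetal_death_allocation": 107,
    "estimated_total_min": 12137,
    "estimated_total_max": 12354,
    "increase_factor": 2.5,
    "coverage_registered_pct": 29.1,
    "coverage_estimated_min_pct": 11.4,
    "fertility_registered_per_1000": 1.70,
    "fertility_estimated_max_per_1000": 4.33,
    "fetal_mortality_ratio_10_13_vs_20_29": 1.28,
}


def compute_reference_estimates(
    inputs: dict[str, float] | None = None,
) -> dict[str, float]:
    """Recompute every headline estimate from the printed components.

    All values are produced by the package's estimation and indicator
    functions; nothing downstream of the inputs is hard-coded.
    """
    c = dict(REFERENCE_INPUTS)
    if inputs:
        c.update(inputs)

    registered = registered_total(
        nv=int(c["live_births_10_13"]),
        fetal=int(c["fetal_deaths_10_13"]),
        maternal_before_end=int(c["maternal_deaths_before_end_10_13"]),
        abortions=int(c["abortion_admissions_10_13"]),
    )
    eligible = int(c["live_births_14_total"]) - int(c["live_births_14_excluded"])
    classification = Classification(
        n_conceived_13=int(c["conceived_at_13"]),
        n_conceived_14=int(c["conceived_at_14"]),
    )
    allocation = allocate_fetal_deaths(
        int(c["fetal_deaths_14"]), classification.proportion
    )
    interval = estimated_total(
        registered=registered,
        extra_live_births=classification.n_conceived_13,
        extra_fetal_deaths=allocation,
        extra_abortions_low=int(c["abortion_extra_low"]),
        extra_abortions_high=int(c["abortion_extra_high"]),
    )
    ratios = comparison_ratios(
        {"fetal_mortality_per_1000": c["fetal_mortality_10_13_per_1000"]},
        {"fetal_mortality_per_1000": c["fetal_mortality_20_29_per_1000"]},
        indicators=("fetal_mortality_per_1000",),
    )
    return {
        "registered_pregnancies": registered,
        "eligible_live_births_14": eligible,
        "conceived_at_13_pct": classification.proportion_pct,
        "fetal_death_allocation": allocation,
        "estimated_total_min": interval.min_count,
        "estimated_total_max": interval.max_count,
        "increase_factor": round_half_up(interval.min_count / registered, 1),
        "coverage_registered_pct": notification_coverage(
            int(c["rape_notifications_10_13"]), registered
        ),
        "coverage_estimated_min_pct": notification_coverage(
            int(c["rape_notifications_10_13"]), interval.max_count
        ),
        "fertility_registered_per_1000": fertility_rate(
            registered, int(c["population_10_13_period"]), int(c["n_years"])
        ),
        "fertility_estimated_max_per_1000": fertility_rate(
            interval.max_count, int(c["population_10_13_period"]), int(c["n_years"])
        ),
        "fetal_mortality_ratio_10_13_vs_20_29": ratios["fetal_mortality_per_1000"],
    }


def verify_reference_arithmetic(
    inputs: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-quantity pass/fail comparison of recomputed vs published values.

    Returns a frame with columns ``quantity``, ``computed``, ``published``,
    ``passed``; equality is at the published printed precision (the values
    are exact desk arithmetic, so no tolerance is needed).
    """
    computed = compute_reference_estimates(inputs)
    rows = [
        {
            "quantity": key,
            "computed": computed[key],
            "published": published,
            "passed": bool(abs(computed[key] - published) < 1e-9),
        }
        for key, published in PUBLISHED.items()
    ]
    return pd.DataFrame(rows)
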