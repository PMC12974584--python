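import pytest

from gestima.synthetic_data import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Degraded cohort at default rates, small enough for fast unit tests."""
    return generate_cohort(
        SimulationConfig(
            seed=7,
            n_regions=4,
            municipalities_per_region=2,
            pregnancies_per_region=500,
            girls_10_13_per_region_year=3000,
        )
    )


@pytest.fixture(scope="session")
def clean_cohort():
    """Undegraded cohort: no missingness, no age errors, no distractors."""
    return generate_cohort(
        SimulationConfig(
            seed=11,
            n_regions=3,
            municipalities_per_region=2,
            pregnancies_per_region=700,
            girls_10_13_per_region_year=3000,
            missing_ga_rate=0.0,
            missing_dob_rate=0.0,
            age_inconsistency_rate=0.0,
            unlinked_notification_rate=0.0,
            distractor_notification_rate=0.0,
        )
    )
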