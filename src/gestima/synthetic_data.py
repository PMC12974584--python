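"""Seeded synthetic record systems with known conception ground truth.

The generator emulates the statistical structure the estimator assumes: each
simulated pregnancy is given a true conception date, a gestational length,
and an outcome (live birth, fetal demise, abortion admission, or maternal
death before the end of pregnancy), with the outcome date equal to
conception + 7 x gestational weeks.  The mother's birth date is then
*back-solved* so that her completed-years age at the outcome hits the target
stratum, and — for age-14 outcomes — so that her age at conception is 13
with a configurable probability ``q``.  Missingness and age inconsistencies
are injected only after the ground truth is recorded, so every degradation
is measurable against truth.

Ages are constructed under the same 365-day completed-years convention the
estimator applies (the default), which isolates method fidelity from
convention artifacts; a ``calendar_age_truth`` toggle instead constructs
ages by calendar birthdays so the bias of the 365-day convention itself can
be studied.

One pregnancy yields exactly one record in exactly one outcome table and
exactly one ground-truth row.  Sexual-violence notifications are generated
per pregnancy with probability ``notification_coverage_true``, plus an
independent stream of notifications not linked to any pregnancy (coverage
above 100% is a real phenomenon where referral services concentrate cases)
and a stream of distractor notifications failing exactly one selection
filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .schema_io import RegionMap, write_table

__all__ = [
    "FILENAMES",
    "OUTCOMES",
    "SimulationConfig",
    "SyntheticCohort",
    "default_birth_weeks_probs",
    "generate_cohort",
    "inject_age_inconsistency",
    "inject_missingness",
]

OUTCOMES = ("live_birth", "fetal_death", "abortion", "maternal_death")

#: Canonical on-disk names for the generated tables, shared with the pipeline.
FILENAMES = {
    "live_births": "live_births.csv",
    "fetal_deaths": "fetal_deaths.csv",
    "maternal_deaths": "maternal_deaths.csv",
    "abortion_admissions": "abortion_admissions.csv",
    "violence_notifications": "violence_notifications.csv",
    "neonatal_deaths": "neonatal_deaths.csv",
    "population": "population.csv",
    "region_map": "region_map.csv",
    "ground_truth": "ground_truth.csv",
}

_TABLE_SCHEMAS = {
    "live_births": "live_birth",
    "fetal_deaths": "fetal_death",
    "maternal_deaths": "maternal_death",
    "abortion_admissions": "abortion_admission",
    "violence_notifications": "violence_notification",
    "neonatal_deaths": "neonatal_death",
    "population": "population",
}


def default_birth_weeks_probs(preterm_mass: float = 0.185) -> dict[int, float]:
    """Discrete gestational-age distribution for births (weeks 22-45, mode 39).

    A preterm component (22-36 weeks, weight rising toward term) carrying
    ``preterm_mass`` of the probability, and a term component peaked at 39
    weeks carrying the rest.  The default preterm mass matches the elevated
    preterm fraction observed in this age group rather than the general
    population's ~11%.
    """
    preterm = {w: float(w - 21) for w in range(22, 37)}
    term = {37: 8.0, 38: 17.0, 39: 30.0, 40: 22.0, 41: 14.0, 42: 6.0, 43: 2.0, 44: 0.7, 45: 0.3}
    p_tot = sum(preterm.values())
    t_tot = sum(term.values())
    probs = {w: preterm_mass * v / p_tot for w, v in preterm.items()}
    probs.update({w: (1.0 - preterm_mass) * v / t_tot for w, v in term.items()})
    return probs


class SimulationConfig(BaseModel):
    """Parameters of the synthetic cohort.

    Defaults emulate the study conditions of the reference setting: a
    19-region state observed 2012-2022 with roughly 18,700 pregnancies at
    maternal ages 10-14 over the period, 62.4% of age-14 deliveries
    conceived at 13, around 10% of age-14 birth certificates degraded beyond
    use, and measured notification coverage near 30% of *registered*
    pregnancies.  Because notifications here are linked per pregnancy at the
    age of conception, the per-pregnancy coverage that reproduces that
    measured value is about 0.11 (coverage measured against all pregnancies,
    including those ending at 14 after conception at 13, is what the true
    rate controls).
    """

    seed: int = 0
    first_year: int = 2012
    last_year: int = 2022
    n_regions: int = Field(19, ge=1)
    municipalities_per_region: int = Field(3, ge=1)
    pregnancies_per_region: int = Field(985, ge=0)
    girls_10_13_per_region_year: int = Field(13600, ge=0)

    #: P(maternal age stratum at outcome), ages 10..14
    age_at_outcome_probs: dict[int, float] = {
        10: 0.01,
        11: 0.03,
        12: 0.06,
        13: 0.16,
        14: 0.74,
    }
    #: P(outcome type); one pregnancy ends in exactly one stream
    outcome_probs: dict[str, float] = {
        "live_birth": 0.89,
        "fetal_death": 0.013,
        "abortion": 0.096,
        "maternal_death": 0.001,
    }
    #: gestational-weeks pmf for births and fetal demises (None -> default)
    gestational_weeks_probs: dict[int, float] | None = None
    abortion_weeks_low: int = Field(6, ge=1)
    abortion_weeks_high: int = Field(21, ge=1)

    #: q — P(conceived at 13 | age 14 at outcome)
    fraction_conceived_at_13: float = Field(0.624, ge=0.0, le=1.0)

    missing_ga_rate: float = Field(0.05, ge=0.0, le=1.0)
    missing_dob_rate: float = Field(0.03, ge=0.0, le=1.0)
    age_inconsistency_rate: float = Field(0.025, ge=0.0, le=1.0)

    notification_coverage_true: float = Field(0.11, ge=0.0, le=1.0)
    unlinked_notification_rate: float = Field(0.01, ge=0.0, le=1.0)
    distractor_notification_rate: float = Field(0.05, ge=0.0, le=1.0)
    legal_abortion_rate_given_notified: float = Field(0.08, ge=0.0, le=1.0)
    neonatal_mortality_rate: float = Field(0.0164, ge=0.0, le=1.0)

    #: construct truth by calendar birthdays instead of the 365-day convention
    calendar_age_truth: bool = False

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.first_year > self.last_year:
            raise ValueError("first_year > last_year")
        if self.abortion_weeks_low >= self.abortion_weeks_high:
            raise ValueError("abortion_weeks_low must be < abortion_weeks_high")
        for name, probs in (
            ("age_at_outcome_probs", self.age_at_outcome_probs),
            ("outcome_probs", self.outcome_probs),
        ):
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"negative probability in {name}")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if set(self.age_at_outcome_probs) - set(range(10, 15)):
            raise ValueError("age_at_outcome_probs keys must lie in 10..14")
        if set(self.outcome_probs) != set(OUTCOMES):
            raise ValueError(f"outcome_probs keys must be {OUTCOMES}")
        if self.gestational_weeks_probs is not None:
            gw = self.gestational_weeks_probs
            if set(gw) - set(range(6, 46)):
                raise ValueError("gestational_weeks_probs keys must lie in 6..45")
            if abs(sum(gw.values()) - 1.0) > 1e-9:
                raise ValueError("gestational_weeks_probs must sum to 1")
        if (
            self.fraction_conceived_at_13 > 0
            and self.age_at_outcome_probs.get(14, 0.0) == 0.0
            and self.pregnancies_per_region > 0
        ):
            raise ValueError(
                "infeasible: fraction_conceived_at_13 > 0 with zero "
                "probability of age-14 outcomes"
            )
        return self

    @property
    def n_years(self) -> int:
        return self.last_year - self.first_year + 1


@dataclass
class SyntheticCohort:
    """Generated tables, region map and per-pregnancy ground truth."""

    live_births: pd.DataFrame
    fetal_deaths: pd.DataFrame
    maternal_deaths: pd.DataFrame
    abortion_admissions: pd.DataFrame
    violence_notifications: pd.DataFrame
    neonatal_deaths: pd.DataFrame
    population: pd.DataFrame
    region_map: RegionMap
    ground_truth: pd.DataFrame
    config: SimulationConfig

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in _TABLE_SCHEMAS}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all tables as CSV into ``outdir``; returns name -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for name, schema in _TABLE_SCHEMAS.items():
            paths[name] = outdir / FILENAMES[name]
            write_table(getattr(self, name), paths[name], schema)
        paths["region_map"] = outdir / FILENAMES["region_map"]
        self.region_map.to_csv(paths["region_map"])
        paths["ground_truth"] = outdir / FILENAMES["ground_truth"]
        gt = self.ground_truth.copy()
        gt["true_conception_date"] = gt["true_conception_date"].dt.strftime("%Y-%m-%d")
        gt["truly_notified"] = gt["truly_notified"].map({True: "true", False: "false"})
        gt.to_csv(paths["ground_truth"], index=False)
        return paths


# ---------------------------------------------------------------------------
# degradation


def inject_missingness(
    records: pd.DataFrame, rates: Mapping[str, float], seed: int
) -> pd.DataFrame:
    """Null out fields at the given per-column Bernoulli rates.

    Returns a copy; the caller's frame (and any recorded ground truth) is
    untouched.  Column dtypes are preserved (datetimes gain ``NaT``,
    nullable integers gain ``NA``).
    """
    for rate in rates.values():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate {rate} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out = records.copy()
    for col, rate in rates.items():
        mask = rng.random(len(out)) < rate
        if mask.any():
            out.loc[mask, col] = (
                pd.NaT if pd.api.types.is_datetime64_any_dtype(out[col]) else pd.NA
            )
    return out


def inject_age_inconsistency(
    records: pd.DataFrame,
    rate: float,
    seed: int,
    column: str = "mother_age_recorded",
) -> pd.DataFrame:
    """Mis-state the recorded age by +-1 year for a Bernoulli fraction of rows."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate {rate} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out = records.copy()
    mask = rng.random(len(out)) < rate
    if mask.any():
        delta = rng.choice([-1, 1], size=int(mask.sum()))
        out.loc[mask, column] = out.loc[mask, column] + delta
    return out


# ---------------------------------------------------------------------------
# generation


def _calendar_age(ref: pd.Timestamp, birth: pd.Timestamp) -> int:
    return ref.year - birth.year - ((ref.month, ref.day) < (birth.month, birth.day))


def _solve_birth_offsets_365(
    ages: np.ndarray, gd: np.ndarray, conceived_13: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Days from mother's birth to outcome satisfying the 365-day age targets.

    For an age-``a`` outcome the offset t must lie in [365a, 365a+364].  For
    age-14 outcomes the conception age floor((t - gd)/365) is forced to 13
    by drawing t in [365*14, 365*14 + gd - 1], or to 14 by drawing in
    [365*14 + gd, 365*14 + 364]; gestations are at most 45 weeks = 315 days,
    so both windows are non-empty.
    """
    lo = 365 * ages.astype(np.int64)
    hi = lo + 364
    is14 = ages == 14
    lo = np.where(is14 & ~conceived_13, lo + gd, lo)
    hi = np.where(is14 & conceived_13, 365 * 14 + gd - 1, hi)
    return lo + (rng.random(len(ages)) * (hi - lo + 1)).astype(np.int64)


def _solve_birth_dates_calendar(
    outcome_dates: pd.Series,
    ages: np.ndarray,
    gd: np.ndarray,
    conceived_13: np.ndarray,
    rng: np.random.Generator,
) -> pd.Series:
    """Back-solve birth dates so *calendar* ages hit the targets (rejection).

    Row-wise rejection sampling; used only when ``calendar_age_truth`` is
    set, to quantify the bias of the 365-day convention.
    """
    births = []
    one_day = pd.Timedelta(days=1)
    for i in range(len(ages)):
        d = outcome_dates.iloc[i]
        a = int(ages[i])
        conception = d - pd.Timedelta(days=int(gd[i]))
        for _ in range(400):
            offset = int(rng.integers(0, 366))
            b = d - pd.DateOffset(years=a) - offset * one_day
            b = pd.Timestamp(b)
            if _calendar_age(d, b) != a:
                continue
            if a == 14:
                want = 13 if conceived_13[i] else 14
                if _calendar_age(conception, b) != want:
                    continue
            births.append(b)
            break
        else:  # pragma: no cover - window always contains solutions
            births.append(b)
    return pd.Series(births, index=outcome_dates.index)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the record systems and ground truth for one synthetic cohort.

    Reproducible: the same config (including seed) yields byte-identical
    tables.  Independent random streams drive cohort structure, record
    degradation and notification behaviour, so changing e.g. the missingness
    rates does not reshuffle the underlying pregnancies.
    """
    ss = np.random.SeedSequence(config.seed)
    s_structure, s_degrade, s_notify, s_neonatal = ss.spawn(4)
    rng = np.random.default_rng(s_structure)

    n = config.n_regions * config.pregnancies_per_region
    region_idx = np.repeat(np.arange(config.n_regions), config.pregnancies_per_region)
    region_ids = np.array([f"R{r + 1:02d}" for r in range(config.n_regions)])
    mun_codes_all = {
        r: [f"M{r + 1:02d}{m + 1:02d}" for m in range(config.municipalities_per_region)]
        for r in range(config.n_regions)
    }
    mun_idx = rng.integers(0, config.municipalities_per_region, size=n)
    municipality = np.array(
        [mun_codes_all[r][m] for r, m in zip(region_idx, mun_idx)], dtype=object
    )

    age_keys = np.array(sorted(config.age_at_outcome_probs))
    age_p = np.array([config.age_at_outcome_probs[k] for k in age_keys], dtype=float)
    ages = rng.choice(age_keys, size=n, p=age_p)

    outcome_keys = np.array(OUTCOMES)
    outcome_p = np.array([config.outcome_probs[k] for k in outcome_keys], dtype=float)
    outcome = rng.choice(outcome_keys, size=n, p=outcome_p)

    gw_probs = config.gestational_weeks_probs or default_birth_weeks_probs()
    gw_keys = np.array(sorted(gw_probs))
    gw_p = np.array([gw_probs[k] for k in gw_keys], dtype=float)
    gw_p = gw_p / gw_p.sum()
    weeks = rng.choice(gw_keys, size=n, p=gw_p)
    is_abortion = outcome == "abortion"
    weeks = np.where(
        is_abortion,
        rng.integers(config.abortion_weeks_low, config.abortion_weeks_high + 1, size=n),
        weeks,
    ).astype(np.int64)
    gd = weeks * 7

    years = rng.integers(config.first_year, config.last_year + 1, size=n)
    day_of_year = rng.integers(0, 365, size=n)
    outcome_date = pd.to_datetime(
        pd.DataFrame({"year": years, "month": 1, "day": 1})
    ) + pd.to_timedelta(day_of_year, unit="D")

    conceived_13 = (ages == 14) & (rng.random(n) < config.fraction_conceived_at_13)

    if config.calendar_age_truth:
        mother_birth_date = _solve_birth_dates_calendar(
            outcome_date, ages, gd, conceived_13, rng
        )
    else:
        t = _solve_birth_offsets_365(ages, gd, conceived_13, rng)
        mother_birth_date = outcome_date - pd.to_timedelta(t, unit="D")

    true_conception = outcome_date - pd.to_timedelta(gd, unit="D")
    if config.calendar_age_truth:
        true_age_conception = np.array(
            [
                _calendar_age(c, b)
                for c, b in zip(true_conception, mother_birth_date)
            ]
        )
        true_age_outcome = np.array(
            [_calendar_age(d, b) for d, b in zip(outcome_date, mother_birth_date)]
        )
    else:
        days_conc = (true_conception - mother_birth_date).dt.days.to_numpy()
        true_age_conception = days_conc // 365
        true_age_outcome = (outcome_date - mother_birth_date).dt.days.to_numpy() // 365

    # stable per-outcome record ids in generation order
    prefixes = {"live_birth": "LB", "fetal_death": "FD", "abortion": "AB", "maternal_death": "MD"}
    counters = {k: 0 for k in prefixes}
    record_id = np.empty(n, dtype=object)
    for i in range(n):
        k = outcome[i]
        counters[k] += 1
        record_id[i] = f"{prefixes[k]}{counters[k]:06d}"

    rng_notify = np.random.default_rng(s_notify)
    truly_notified = rng_notify.random(n) < config.notification_coverage_true

    ground_truth = pd.DataFrame(
        {
            "record_id": record_id,
            "outcome_type": outcome,
            "region_id": region_ids[region_idx],
            "true_conception_date": true_conception,
            "true_age_at_conception": true_age_conception,
            "true_age_at_outcome": true_age_outcome,
            "truly_notified": truly_notified,
        }
    )

    # ------------------------------------------------------------------ tables
    lb = outcome == "live_birth"
    preterm = weeks < 37
    weight = np.where(
        preterm,
        rng.normal(2250.0, 650.0, size=n),
        rng.normal(3150.0, 450.0, size=n),
    )
    weight = np.clip(np.round(weight), 400, 5500).astype(np.int64)

    live_births = pd.DataFrame(
        {
            "record_id": record_id[lb],
            "mother_birth_date": mother_birth_date[lb],
            "infant_birth_date": outcome_date[lb],
            "gestational_weeks": pd.array(weeks[lb], dtype="Int64"),
            "mother_age_recorded": pd.array(true_age_outcome[lb], dtype="Int64"),
            "municipality_code": municipality[lb],
            "infant_birth_weight_g": pd.array(weight[lb], dtype="Int64"),
        }
    ).reset_index(drop=True)

    fd = outcome == "fetal_death"
    fetal_deaths = pd.DataFrame(
        {
            "record_id": record_id[fd],
            "outcome_date": outcome_date[fd],
            "mother_age_recorded": pd.array(true_age_outcome[fd], dtype="Int64"),
            "municipality_code": municipality[fd],
        }
    ).reset_index(drop=True)

    md = outcome == "maternal_death"
    maternal_deaths = pd.DataFrame(
        {
            "record_id": record_id[md],
            "death_date": outcome_date[md],
            "mother_age_recorded": pd.array(true_age_outcome[md], dtype="Int64"),
            "died_before_pregnancy_end": pd.array([True] * int(md.sum()), dtype="boolean"),
            "municipality_code": municipality[md],
        }
    ).reset_index(drop=True)

    ab = is_abortion
    base_codes = rng_notify.choice(
        np.array(["O00", "O02", "O03", "O05", "O06"]),
        size=n,
        p=np.array([0.05, 0.05, 0.60, 0.05, 0.25]),
    )
    legal = truly_notified & (
        rng_notify.random(n) < config.legal_abortion_rate_given_notified
    )
    icd = np.where(legal, "O04", base_codes)
    abortion_admissions = pd.DataFrame(
        {
            "record_id": record_id[ab],
            "admission_date": outcome_date[ab],
            "mother_birth_date": mother_birth_date[ab],
            "mother_age_recorded": pd.array(true_age_outcome[ab], dtype="Int64"),
            "icd10_code": icd[ab],
            "municipality_code": municipality[ab],
        }
    ).reset_index(drop=True)

    rng_neo = np.random.default_rng(s_neonatal)
    neo_mask = lb & (rng_neo.random(n) < config.neonatal_mortality_rate)
    neo_age_days = rng_neo.integers(0, 28, size=n)
    neo_idx = np.flatnonzero(neo_mask)
    neonatal_deaths = pd.DataFrame(
        {
            "record_id": [f"ND{i + 1:06d}" for i in range(len(neo_idx))],
            "death_date": (
                outcome_date.iloc[neo_idx] + pd.to_timedelta(neo_age_days[neo_idx], unit="D")
            ).reset_index(drop=True),
            "age_days": pd.array(neo_age_days[neo_idx], dtype="Int64"),
            "municipality_code": municipality[neo_idx],
        }
    ).reset_index(drop=True)

    # ------------------------------------------------------- notifications
    notif_frames = []
    linked_idx = np.flatnonzero(truly_notified)
    notif_frames.append(
        pd.DataFrame(
            {
                "record_id": [f"VN{i + 1:06d}" for i in range(len(linked_idx))],
                "victim_sex": "female",
                "victim_age": pd.array(true_age_conception[linked_idx], dtype="Int64"),
                "occurrence_date": true_conception.iloc[linked_idx].reset_index(drop=True),
                "rape_flag": pd.array([True] * len(linked_idx), dtype="boolean"),
                "municipality_code": municipality[linked_idx],
            }
        )
    )

    def _random_notifications(count: int, tag: str, kind: np.ndarray | None) -> pd.DataFrame:
        r_idx = rng_notify.integers(0, config.n_regions, size=count)
        m_idx = rng_notify.integers(0, config.municipalities_per_region, size=count)
        years_u = rng_notify.integers(config.first_year, config.last_year + 1, size=count)
        doy = rng_notify.integers(0, 365, size=count)
        dates = pd.to_datetime(
            pd.DataFrame({"year": years_u, "month": 1, "day": 1})
        ) + pd.to_timedelta(doy, unit="D")
        age = rng_notify.integers(10, 14, size=count)
        sex = np.full(count, "female", dtype=object)
        flag = np.full(count, True)
        if kind is not None:  # distractors: break exactly one filter each
            age = np.where(kind == 1, rng_notify.integers(14, 18, size=count), age)
            sex = np.where(kind == 0, "male", sex)
            flag = np.where(kind == 2, False, flag)
        return pd.DataFrame(
            {
                "record_id": [f"{tag}{i + 1:06d}" for i in range(count)],
                "victim_sex": sex,
                "victim_age": pd.array(age, dtype="Int64"),
                "occurrence_date": dates,
                "rape_flag": pd.array(flag, dtype="boolean"),
                "municipality_code": [
                    mun_codes_all[r][m] for r, m in zip(r_idx, m_idx)
                ],
            }
        )

    n_unlinked = int(rng_notify.binomial(n, config.unlinked_notification_rate)) if n else 0
    if n_unlinked:
        notif_frames.append(_random_notifications(n_unlinked, "VU", kind=None))
    n_distract = int(rng_notify.binomial(n, config.distractor_notification_rate)) if n else 0
    if n_distract:
        kind = rng_notify.integers(0, 3, size=n_distract)
        notif_frames.append(_random_notifications(n_distract, "VD", kind=kind))
    violence_notifications = pd.concat(notif_frames, ignore_index=True)

    # ------------------------------------------------------- population, map
    population = pd.DataFrame(
        [
            {"region_id": region_ids[r], "year": y, "girls_10_13": config.girls_10_13_per_region_year}
            for r in range(config.n_regions)
            for y in range(config.first_year, config.last_year + 1)
        ]
    )
    population["year"] = population["year"].astype("Int64")
    population["girls_10_13"] = population["girls_10_13"].astype("Int64")

    region_map = RegionMap(
        municipality_to_region={
            code: region_ids[r]
            for r, codes in mun_codes_all.items()
            for code in codes
        },
        region_names={region_ids[r]: f"Health Region {r + 1:02d}" for r in range(config.n_regions)},
    )

    # ------------------------------------------------- degrade (truth fixed)
    d1, d2, d3 = s_degrade.spawn(3)

    def _seed(s: np.random.SeedSequence) -> int:
        return int(s.generate_state(1)[0] % (2**31))

    live_births = inject_missingness(
        live_births,
        {"gestational_weeks": config.missing_ga_rate, "mother_birth_date": config.missing_dob_rate},
        seed=_seed(d1),
    )
    live_births = inject_age_inconsistency(
        live_births, config.age_inconsistency_rate, seed=_seed(d2)
    )
    abortion_admissions = inject_missingness(
        abortion_admissions, {"mother_birth_date": config.missing_dob_rate}, seed=_seed(d3)
    )

    return SyntheticCohort(
        live_births=live_births,
        fetal_deaths=fetal_deaths,
        maternal_deaths=maternal_deaths,
        abortion_admissions=abortion_admissions,
        violence_notifications=violence_notifications,
        neonatal_deaths=neonatal_deaths,
        population=population,
        region_map=region_map,
        ground_truth=ground_truth,
        config=config,
    )
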