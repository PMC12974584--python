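"""End-to-end pipeline: read, clean, estimate, and tabulate indicators.

Stages (each logged with record counts in a manifest, so the manifest itself
reproduces the estimation tree):

1. read the seven tables and region map, collecting rejects per table;
2. annotate every record table with its health region;
3. registered pregnancies = outcomes at recorded maternal age 10-13 in the
   period (maternal deaths only when they occurred before the end of
   pregnancy), summed over the four streams per region and for the state;
4. age-14 live births -> eligibility filter -> classification by imputed
   conception age -> the conceived-at-13 proportion p;
5. age-14 fetal deaths allocated by p; age-14 abortion admissions bounded by
   the two gestational-age scenarios;
6. the interval estimate of total pregnancies at ages 10-13;
7. rape-notification selection and coverage; fertility rates; perinatal
   indicators — one indicator row per region plus a state row.

The pipeline is a pure function of its inputs and configuration: rerunning
on the same files yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .conception_estimation import (
    Classification,
    EstimateInterval,
    ScenarioBounds,
    ScenarioCounts,
    abortion_scenario_counts,
    allocate_fetal_deaths,
    classify_live_births_14,
    estimated_total,
    registered_total,
)
from .eligibility import ExclusionReport, filter_14yo_live_births
from .indicators import (
    INDICATOR_COLUMNS,
    fertility_rate,
    notification_coverage,
    perinatal_indicators,
    select_rape_notifications,
)
from .schema_io import RegionMap, StudyPeriod, map_region, read_table, write_table
from .synthetic_data import FILENAMES

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

STATE = "STATE"  # stratum key for the all-regions aggregate


class PipelineConfig(BaseModel):
    """Paths, period and scenario parameters of one pipeline run."""

    live_births: Path
    fetal_deaths: Path
    maternal_deaths: Path
    abortion_admissions: Path
    violence_notifications: Path
    neonatal_deaths: Path
    population: Path
    region_map: Path
    outdir: Path
    first_year: int = 2012
    last_year: int = 2022
    ga_low_weeks: int = Field(6, ge=1)
    ga_high_weeks: int = Field(21, ge=1)
    date_format: str = "iso"

    @classmethod
    def from_dir(cls, indir: str | Path, outdir: str | Path, **overrides: Any) -> "PipelineConfig":
        """Config for a directory laid out with the canonical file names."""
        indir = Path(indir)
        paths = {
            name: indir / FILENAMES[name]
            for name in (
                "live_births",
                "fetal_deaths",
                "maternal_deaths",
                "abortion_admissions",
                "violence_notifications",
                "neonatal_deaths",
                "population",
                "region_map",
            )
        }
        return cls(outdir=Path(outdir), **paths, **overrides)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    @property
    def period(self) -> StudyPeriod:
        return StudyPeriod(self.first_year, self.last_year)

    @property
    def bounds(self) -> ScenarioBounds:
        return ScenarioBounds(self.ga_low_weeks, self.ga_high_weeks)


@dataclass
class PipelineResult:
    estimate: EstimateInterval
    exclusion: ExclusionReport
    classification: Classification | None
    scenario: ScenarioCounts
    indicators: pd.DataFrame
    manifest: dict[str, Any]


def _in_period(dates: pd.Series, period: StudyPeriod) -> pd.Series:
    return period.contains_year(dates.dt.year).fillna(False)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and persist outputs plus a stage-count manifest."""
    period = config.period
    manifest: dict[str, Any] = {
        "period": {"first_year": period.first_year, "last_year": period.last_year},
        "stages": {},
    }
    region_map = RegionMap.from_csv(config.region_map)

    tables: dict[str, pd.DataFrame] = {}
    rejects: dict[str, pd.DataFrame] = {}
    schema_of = {
        "live_births": "live_birth",
        "fetal_deaths": "fetal_death",
        "maternal_deaths": "maternal_death",
        "abortion_admissions": "abortion_admission",
        "violence_notifications": "violence_notification",
        "neonatal_deaths": "neonatal_death",
        "population": "population",
    }
    read_counts: dict[str, Any] = {}
    for name, schema in schema_of.items():
        df, rej = read_table(getattr(config, name), schema, date_format=config.date_format)
        if name != "population":
            df = map_region(df, region_map)
        tables[name] = df
        rejects[name] = rej
        read_counts[name] = {"rows": int(len(df) + len(rej)), "accepted": int(len(df)), "rejected": int(len(rej))}
    manifest["stages"]["read"] = read_counts

    # ------------------------------------------------ registered pregnancies
    lb = tables["live_births"]
    fd = tables["fetal_deaths"]
    md = tables["maternal_deaths"]
    ab = tables["abortion_admissions"]

    date_col = {
        "live_births": "infant_birth_date",
        "fetal_deaths": "outcome_date",
        "maternal_deaths": "death_date",
        "abortion_admissions": "admission_date",
    }
    reg_masks = {
        "live_births": lb["mother_age_recorded"].between(10, 13).fillna(False),
        "fetal_deaths": fd["mother_age_recorded"].between(10, 13).fillna(False),
        "maternal_deaths": md["mother_age_recorded"].between(10, 13).fillna(False)
        & md["died_before_pregnancy_end"].fillna(False).astype(bool),
        "abortion_admissions": ab["mother_age_recorded"].between(10, 13).fillna(False),
    }
    registered_by_region: dict[str, pd.Series] = {}
    registered_counts: dict[str, int] = {}
    for name, mask in reg_masks.items():
        df = tables[name]
        sel = df.loc[mask & _in_period(df[date_col[name]], period)]
        registered_counts[name] = int(len(sel))
        registered_by_region[name] = sel.groupby("region_id").size()
    registered = registered_total(
        nv=registered_counts["live_births"],
        fetal=registered_counts["fetal_deaths"],
        maternal_before_end=registered_counts["maternal_deaths"],
        abortions=registered_counts["abortion_admissions"],
    )
    manifest["stages"]["registered"] = {**registered_counts, "total": registered}

    # ------------------------------------------------------- age-14 extras
    lb14 = lb.loc[
        (lb["mother_age_recorded"] == 14).fillna(False)
        & _in_period(lb["infant_birth_date"], period)
    ]
    eligible, exclusion = filter_14yo_live_births(lb14)
    classification: Classification | None = None
    p_notes: list[str] = []
    if len(eligible):
        classification = classify_live_births_14(eligible)
        extra_lb = classification.n_conceived_13
        p = classification.proportion
    else:
        # no usable age-14 certificates: the proportion is undefined and no
        # extras can be allocated; recorded in the manifest, not fatal
        extra_lb, p = 0, 0.0
        p_notes.append("no eligible age-14 live births; extras set to 0")

    fd14 = fd.loc[
        (fd["mother_age_recorded"] == 14).fillna(False)
        & _in_period(fd["outcome_date"], period)
    ]
    extra_fd = allocate_fetal_deaths(len(fd14), p)

    ab14 = ab.loc[
        (ab["mother_age_recorded"] == 14).fillna(False)
        & _in_period(ab["admission_date"], period)
    ]
    scenario = abortion_scenario_counts(ab14, config.bounds)

    estimate = estimated_total(
        registered=registered,
        extra_live_births=extra_lb,
        extra_fetal_deaths=extra_fd,
        extra_abortions_low=scenario.count_low,
        extra_abortions_high=scenario.count_high,
    )
    manifest["stages"]["age14"] = {
        "live_births_total": int(len(lb14)),
        "live_births_excluded": exclusion.excluded_count,
        "live_births_eligible": exclusion.eligible_count,
        "conceived_at_13": classification.n_conceived_13 if classification else 0,
        "conceived_at_14": classification.n_conceived_14 if classification else 0,
        "proportion_pct": classification.proportion_pct if classification else None,
        "fetal_deaths_total": int(len(fd14)),
        "fetal_deaths_allocated": extra_fd,
        "abortions_total": int(len(ab14)),
        "abortions_missing_birth_date": scenario.n_missing_birth_date,
        "abortions_scenario_low": scenario.count_low,
        "abortions_scenario_high": scenario.count_high,
        "notes": p_notes,
    }
    manifest["stages"]["estimate"] = {
        "min": estimate.min_count,
        "max": estimate.max_count,
        "components": dict(estimate.components),
    }

    # --------------------------------------------------------- indicators
    notif = tables["violence_notifications"]
    notif_state = select_rape_notifications(notif, period)
    notif_region = select_rape_notifications(notif, period, by_region=True)

    pop = tables["population"]
    pop = pop.loc[period.contains_year(pop["year"].astype(int))]
    pop_by_region = pop.groupby("region_id")["girls_10_13"].sum()
    pop_state = int(pop_by_region.sum())

    neo = tables["neonatal_deaths"]
    neo_in = neo.loc[_in_period(neo["death_date"], period)]

    def stratum_row(region: str | None) -> dict[str, Any]:
        if region is None:
            sel = lambda name: tables[name]  # noqa: E731 - tiny closures
            n_reg = registered
            n_notif = int(notif_state)
            pop_total = pop_state
        else:
            sel = lambda name: tables[name].loc[tables[name]["region_id"] == region]  # noqa: E731
            n_reg = int(sum(registered_by_region[t].get(region, 0) for t in registered_by_region))
            n_notif = int(notif_region.get(region, 0))
            pop_total = int(pop_by_region.get(region, 0))
        lb_s = sel("live_births")
        lb_s = lb_s.loc[
            lb_s["mother_age_recorded"].between(10, 13).fillna(False)
            & _in_period(lb_s["infant_birth_date"], period)
        ]
        fd_s = sel("fetal_deaths")
        fd_s = fd_s.loc[
            fd_s["mother_age_recorded"].between(10, 13).fillna(False)
            & _in_period(fd_s["outcome_date"], period)
        ]
        md_s = sel("maternal_deaths")
        md_s = md_s.loc[
            md_s["mother_age_recorded"].between(10, 13).fillna(False)
            & _in_period(md_s["death_date"], period)
        ]
        ab_s = sel("abortion_admissions")
        ab_s = ab_s.loc[
            ab_s["mother_age_recorded"].between(10, 13).fillna(False)
            & _in_period(ab_s["admission_date"], period)
        ]
        neo_s = neo_in if region is None else neo_in.loc[neo_in["region_id"] == region]
        peri = perinatal_indicators(lb_s, fd_s, neo_s, md_s, ab_s, n_notif)
        row: dict[str, Any] = {
            "stratum": STATE if region is None else region,
            "age_group": "10-13",
            "period": f"{period.first_year}-{period.last_year}",
            "pregnancies_registered": n_reg,
            "pregnancies_estimated_min": estimate.min_count if region is None else None,
            "pregnancies_estimated_max": estimate.max_count if region is None else None,
            "population_girls_10_13": pop_total,
            "fertility_rate_per_1000": (
                fertility_rate(n_reg, pop_total, period.n_years) if pop_total > 0 else None
            ),
            "notifications": n_notif,
            "coverage_pct": notification_coverage(n_notif, n_reg) if n_reg > 0 else None,
        }
        row.update(peri)
        return row

    rows = [stratum_row(None)] + [stratum_row(r) for r in region_map.region_ids]
    indicators = pd.DataFrame(rows)
    front = ["stratum", "age_group", "period"]
    ordered = front + [c for c in INDICATOR_COLUMNS if c in indicators.columns]
    ordered += [c for c in indicators.columns if c not in ordered]
    indicators = indicators.loc[:, ordered]

    manifest["stages"]["indicators"] = {
        "notifications_state": int(notif_state),
        "population_state": pop_state,
        "n_strata": int(len(indicators)),
    }
    manifest["conservation"] = {
        "eligibility_partition": exclusion.eligible_count + exclusion.excluded_count
        == exclusion.input_count,
        "registered_regions_sum": int(
            sum(int(s.sum()) for s in registered_by_region.values())
        )
        == registered,
        "estimate_bounds": estimate.min_count <= estimate.max_count
        and estimate.min_count >= registered,
    }

    _persist(config, eligible, exclusion, estimate, indicators, rejects, manifest)
    return PipelineResult(
        estimate=estimate,
        exclusion=exclusion,
        classification=classification,
        scenario=scenario,
        indicators=indicators,
        manifest=manifest,
    )


def _persist(
    config: PipelineConfig,
    eligible: pd.DataFrame,
    exclusion: ExclusionReport,
    estimate: EstimateInterval,
    indicators: pd.DataFrame,
    rejects: dict[str, pd.DataFrame],
    manifest: dict[str, Any],
) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(
        eligible.drop(columns=["region_id"]),
        outdir / "eligible_live_births_14.csv",
        "live_birth",
    )
    exclusion.to_frame().to_csv(outdir / "exclusion_report.csv", index=False)
    with open(outdir / "estimate.json", "w") as fh:
        json.dump(
            {
                "min_count": estimate.min_count,
                "max_count": estimate.max_count,
                "components": dict(estimate.components),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    indicators.to_csv(outdir / "indicators.csv", index=False)
    for name, rej in rejects.items():
        if len(rej):
            rej.to_csv(outdir / f"rejects_{name}.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def summary_text(result: PipelineResult) -> str:
    """Human-readable headline summary of a pipeline run."""
    est = result.estimate
    c = est.components
    state = result.indicators.iloc[0]
    lines = [
        f"Registered pregnancies at ages 10-13: {c['registered']:,} "
        f"(live births + fetal deaths + maternal deaths before pregnancy end "
        f"+ abortion admissions).",
        f"Age-14 live births: {result.exclusion.input_count:,} records, "
        f"{result.exclusion.excluded_count:,} excluded, "
        f"{result.exclusion.eligible_count:,} eligible.",
    ]
    if result.classification is not None:
        lines.append(
            f"Conceived at 13 among eligible age-14 deliveries: "
            f"{result.classification.n_conceived_13:,} "
            f"({result.classification.proportion_pct}%)."
        )
    lines += [
        f"Estimated pregnancies at ages 10-13 (incl. age-14 outcomes conceived "
        f"at 13): between {est.min_count:,} and {est.max_count:,}.",
        f"State fertility rate (registered): "
        f"{state['fertility_rate_per_1000']} per 1,000; rape-notification "
        f"coverage (registered denominator): {state['coverage_pct']}%.",
    ]
    return "\n".join(lines)
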