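"""Schemas, CSV I/O and region mapping for simplified vital-records extracts.

The pipeline consumes flat CSV extracts modelled on the Brazilian national
health information systems: live-birth certificates (SINASC), fetal and
maternal death certificates (SIM), hospital abortion admissions (SIH/SUS,
ICD-10 O00-O08) and sexual-violence notifications (SINAN), plus a population
series for girls aged 10-13 and a municipality -> health-region lookup.

Conventions
-----------
* Dates are ISO-8601 (``YYYY-MM-DD``) by default; the raw DATASUS
  ``ddmmyyyy`` dialect is available as a reader option.
* Missing values are empty strings on disk and pandas ``NA`` in memory.
* DATASUS-style "ignored" sentinels (gestational weeks ``99``, maternal age
  ``99``, birth weight ``9999``) are normalised to missing at read time.
* Rows violating hard type constraints (unparseable dates, non-integer
  counts, out-of-range values) are never silently dropped: they are returned
  in a rejects table carrying a ``reject_reason`` column.

Record collections are plain :class:`pandas.DataFrame` objects whose columns
and dtypes are fixed by the :data:`SCHEMAS` registry; every downstream module
operates on these frames.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "SCHEMAS",
    "RegionMap",
    "RegionMapError",
    "Schema",
    "SchemaError",
    "StudyPeriod",
    "icd10_category",
    "is_legal_abortion",
    "map_region",
    "read_table",
    "write_table",
]

_DATE_FORMATS = {"iso": "%Y-%m-%d", "ddmmyyyy": "%d%m%Y"}

_TRUE_TOKENS = frozenset({"true", "t", "1", "yes", "sim"})
_FALSE_TOKENS = frozenset({"false", "f", "0", "no", "nao"})


class SchemaError(ValueError):
    """Malformed table: unknown schema, missing columns or duplicate keys."""


class RegionMapError(KeyError):
    """Municipality codes not covered by the region map."""

    def __str__(self) -> str:  # KeyError quotes its payload; keep it readable
        return self.args[0] if self.args else ""


@dataclass(frozen=True)
class Column:
    """One column of a record schema.

    ``required`` columns reject the row when empty; optional columns become
    ``NA``.  ``bounds`` are inclusive and checked only on present values.
    ``sentinels`` are on-disk tokens normalised to missing before parsing.
    """

    name: str
    kind: str  # "str" | "int" | "date" | "bool"
    required: bool = True
    bounds: tuple[int, int] | None = None
    sentinels: frozenset[str] = frozenset()


@dataclass(frozen=True)
class Schema:
    name: str
    columns: tuple[Column, ...]
    key: tuple[str, ...] = ("record_id",)

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]


SCHEMAS: dict[str, Schema] = {
    s.name: s
    for s in (
        Schema(
            "live_birth",
            (
                Column("record_id", "str"),
                Column("mother_birth_date", "date", required=False),
                Column("infant_birth_date", "date"),
                Column(
                    "gestational_weeks",
                    "int",
                    required=False,
                    bounds=(6, 45),
                    sentinels=frozenset({"99"}),
                ),
                Column(
                    "mother_age_recorded",
                    "int",
                    required=False,
                    bounds=(8, 60),
                    sentinels=frozenset({"99"}),
                ),
                Column("municipality_code", "str"),
                Column(
                    "infant_birth_weight_g",
                    "int",
                    required=False,
                    bounds=(1, 9000),
                    sentinels=frozenset({"9999"}),
                ),
            ),
        ),
        Schema(
            "fetal_death",
            (
                Column("record_id", "str"),
                Column("outcome_date", "date"),
                # intake filter: implausible maternal ages go to rejects
                Column("mother_age_recorded", "int", bounds=(10, 55)),
                Column("municipality_code", "str"),
            ),
        ),
        Schema(
            "maternal_death",
            (
                Column("record_id", "str"),
                Column("death_date", "date"),
                Column("mother_age_recorded", "int", bounds=(8, 60)),
                Column("died_before_pregnancy_end", "bool"),
                Column("municipality_code", "str"),
            ),
        ),
        Schema(
            "abortion_admission",
            (
                Column("record_id", "str"),
                Column("admission_date", "date"),
                Column("mother_birth_date", "date", required=False),
                Column(
                    "mother_age_recorded",
                    "int",
                    bounds=(8, 60),
                    sentinels=frozenset({"99"}),
                ),
                Column("icd10_code", "str"),
                Column("municipality_code", "str"),
            ),
        ),
        Schema(
            "violence_notification",
            (
                Column("record_id", "str"),
                Column("victim_sex", "str"),
                Column("victim_age", "int", bounds=(0, 120)),
                Column("occurrence_date", "date"),
                Column("rape_flag", "bool"),
                Column("municipality_code", "str"),
            ),
        ),
        Schema(
            "neonatal_death",
            (
                Column("record_id", "str"),
                Column("death_date", "date"),
                Column("age_days", "int", bounds=(0, 27)),
                Column("municipality_code", "str"),
            ),
        ),
        Schema(
            "population",
            (
                Column("region_id", "str"),
                Column("year", "int", bounds=(1900, 2200)),
                Column("girls_10_13", "int", bounds=(0, 10**9)),
            ),
            key=("region_id", "year"),
        ),
    )
}


def _get_schema(schema_name: str) -> Schema:
    try:
        return SCHEMAS[schema_name]
    except KeyError:
        raise SchemaError(
            f"unknown schema {schema_name!r}; known: {sorted(SCHEMAS)}"
        ) from None


def read_table(
    path: str | Path, schema_name: str, date_format: str = "iso"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a CSV extract into a typed frame plus a rejects report.

    Parameters
    ----------
    path
        CSV file with a header matching the schema's column dictionary.
    schema_name
        One of the keys of :data:`SCHEMAS`.
    date_format
        ``"iso"`` (default) or ``"ddmmyyyy"`` for raw DATASUS-style dates.

    Returns
    -------
    (records, rejects)
        ``records`` is the typed collection; ``rejects`` holds the original
        string values of every row that violated a hard constraint, with a
        ``reject_reason`` column (semicolon-joined when a row carries
        several reasons).

    Raises
    ------
    SchemaError
        Unknown schema, missing header columns, or duplicate key values.
    """
    schema = _get_schema(schema_name)
    if date_format not in _DATE_FORMATS:
        raise SchemaError(f"unknown date_format {date_format!r}")
    fmt = _DATE_FORMATS[date_format]

    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in schema.column_names if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing columns {missing_cols} for schema {schema.name}")
    raw = raw.loc[:, schema.column_names].reset_index(drop=True)

    dup = raw.duplicated(subset=list(schema.key), keep=False)
    if dup.any():
        ids = sorted(
            raw.loc[dup, list(schema.key)].astype(str).agg("/".join, axis=1).unique()
        )
        raise SchemaError(
            f"{path}: duplicate {'+'.join(schema.key)} values: {ids[:10]}"
            + (" ..." if len(ids) > 10 else "")
        )

    reasons = np.full(len(raw), "", dtype=object)

    def flag(mask: pd.Series, why: str) -> None:
        m = np.asarray(mask.fillna(False), dtype=bool)
        reasons[m] = np.where(reasons[m] == "", why, reasons[m] + ";" + why)

    out: dict[str, pd.Series] = {}
    for col in schema.columns:
        s = raw[col.name].str.strip()
        s = s.mask(s.isin(col.sentinels), "")
        empty = s == ""
        if col.required:
            flag(empty, f"missing_{col.name}")
        s = s.mask(empty)
        if col.kind == "date":
            parsed = pd.to_datetime(s, format=fmt, errors="coerce")
            flag(~empty & parsed.isna(), f"unparseable_date_{col.name}")
            out[col.name] = parsed
        elif col.kind == "int":
            num = pd.to_numeric(s, errors="coerce")
            bad = ~empty & (num.isna() | (num.notna() & (num % 1 != 0)))
            flag(bad, f"unparseable_int_{col.name}")
            num = num.mask(bad)
            if col.bounds is not None:
                lo, hi = col.bounds
                oob = num.notna() & ((num < lo) | (num > hi))
                flag(oob, f"out_of_range_{col.name}")
                num = num.mask(oob)
            out[col.name] = num.astype("Int64")
        elif col.kind == "bool":
            low = s.str.lower()
            t = low.isin(_TRUE_TOKENS)
            f = low.isin(_FALSE_TOKENS)
            flag(~empty & ~t & ~f, f"unparseable_bool_{col.name}")
            out[col.name] = pd.Series(t, dtype="boolean").mask(~t & ~f)
        else:
            out[col.name] = s
    typed = pd.DataFrame(out, index=raw.index)

    bad_rows = reasons != ""
    rejects = raw.loc[bad_rows].copy()
    rejects["reject_reason"] = reasons[bad_rows]
    records = typed.loc[~bad_rows].reset_index(drop=True)
    return records, rejects.reset_index(drop=True)


def write_table(records: pd.DataFrame, path: str | Path, schema_name: str) -> None:
    """Write a typed collection back to the CSV dialect :func:`read_table` reads.

    Dates are ISO-8601, missing values empty strings, booleans
    ``true``/``false``; the write -> read round trip is lossless.
    """
    schema = _get_schema(schema_name)
    out: dict[str, pd.Series] = {}
    for col in schema.columns:
        s = records[col.name]
        if col.kind == "date":
            out[col.name] = s.dt.strftime("%Y-%m-%d").fillna("")
        elif col.kind == "int":
            out[col.name] = s.astype("Int64").map(
                lambda v: "" if pd.isna(v) else str(int(v))
            )
        elif col.kind == "bool":
            out[col.name] = s.map(
                lambda v: "" if pd.isna(v) else ("true" if v else "false")
            )
        else:
            out[col.name] = s.fillna("")
    pd.DataFrame(out).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# region mapping


@dataclass
class RegionMap:
    """Total mapping municipality code -> health region (URS).

    Health regions group geographically close municipalities for service
    management; every record is aggregated to its region of residence.  The
    map must cover every municipality code appearing in any record — an
    unmapped code is an error, never a silent drop.
    """

    municipality_to_region: dict[str, str]
    region_names: dict[str, str] = field(default_factory=dict)

    @property
    def region_ids(self) -> list[str]:
        return sorted(set(self.municipality_to_region.values()))

    def region_of(self, municipality_code: str) -> str:
        try:
            return self.municipality_to_region[municipality_code]
        except KeyError:
            raise RegionMapError(f"unmapped municipality_code {municipality_code!r}") from None

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionMap":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        for needed in ("municipality_code", "region_id"):
            if needed not in df.columns:
                raise SchemaError(f"{path}: region map needs column {needed!r}")
        mapping = dict(zip(df["municipality_code"], df["region_id"]))
        if len(mapping) != len(df):
            raise SchemaError(f"{path}: duplicate municipality codes in region map")
        names: dict[str, str] = {}
        if "region_name" in df.columns:
            names = dict(zip(df["region_id"], df["region_name"]))
        return cls(mapping, names)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {
                "municipality_code": m,
                "region_id": r,
                "region_name": self.region_names.get(r, r),
            }
            for m, r in sorted(self.municipality_to_region.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.municipality_to_region.items()),
            columns=["municipality_code", "region_id"],
        )


def map_region(records: pd.DataFrame, region_map: RegionMap) -> pd.DataFrame:
    """Annotate records with their health region of residence.

    Conserves record counts exactly: the returned frame has the same rows as
    the input plus a ``region_id`` column.

    Raises
    ------
    RegionMapError
        Listing every distinct unmapped municipality code.
    """
    codes = records["municipality_code"]
    mapped = codes.map(region_map.municipality_to_region)
    unknown = codes[mapped.isna()]
    if len(unknown):
        offenders = sorted(x if pd.notna(x) else "<missing>" for x in unknown.unique())
        raise RegionMapError(f"unmapped municipality codes: {offenders}")
    out = records.copy()
    out["region_id"] = mapped
    return out


# ---------------------------------------------------------------------------
# period and ICD conventions


@dataclass(frozen=True)
class StudyPeriod:
    """Inclusive calendar-year window of the analysis (default 2012-2022).

    A pregnancy belongs to the period through the calendar year of its
    outcome date (delivery, fetal demise, abortion admission or maternal
    death); a violence notification through the year the aggression
    occurred.
    """

    first_year: int = 2012
    last_year: int = 2022

    def __post_init__(self) -> None:
        if self.first_year > self.last_year:
            raise ValueError(f"first_year {self.first_year} > last_year {self.last_year}")

    @property
    def n_years(self) -> int:
        return self.last_year - self.first_year + 1

    @property
    def years(self) -> range:
        return range(self.first_year, self.last_year + 1)

    def contains_year(self, year: "int | pd.Series"):
        if isinstance(year, pd.Series):
            return year.between(self.first_year, self.last_year)
        return self.first_year <= year <= self.last_year


_ICD_ABORTION = re.compile(r"^O0[0-8]")


def icd10_category(code: str) -> str:
    """Normalise an ICD-10 code to its three-character category (``O034`` -> ``O03``)."""
    cat = str(code).strip().upper().replace(".", "")[:3]
    return cat


def is_abortion_code(code: str) -> bool:
    """True for the abortive-outcome block O00-O08."""
    return bool(_ICD_ABORTION.match(icd10_category(code)))


def is_legal_abortion(code: str) -> bool:
    """Legal (induced, medical/legal indication) abortion is category O04 exactly."""
    return icd10_category(code) == "O04"
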