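"""Nest encounter histories and daily covariates.

A monitored nest is summarised by three day-of-season dates: the day it was
found with at least one egg (``day_found``, *i*), the last day it was known
to be active (``day_last_active``, *j*) and the day its fate was confirmed
(``day_fate_confirmed``, *k*).  A successful nest has *j* = *k*; for a failed
nest the failure happened somewhere in the interval (*j*, *k*].  Daily
covariates (soil-surface temperature, near-surface wind speed, rainfall,
solar irradiance and their one-day lags) are carried in a long-format table
with one row per nest per day.

A day index *t* denotes the interval from the midnight starting day *t* to
the next midnight; a nest "survived day *t*" if it was still active at the
following midnight.  Covariates for day *t* are that calendar day's values.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

REGIONS = ("Alsace", "HautsDeFrance")
METHODS = ("camera", "visits")
HABITATS = ("crop", "other")
CLUTCH_CLASSES = ("lt4", "eq4")
FATES = (
    "hatched",
    "agriculture",
    "abandoned",
    "flooded",
    "depredated",
    "unknown_failure",
    "undetermined",
)
#: Failure categories (everything terminal except hatching and the
#: excluded "undetermined" class).
FAILURE_FATES = ("agriculture", "abandoned", "flooded", "depredated", "unknown_failure")

NEST_COLUMNS = [
    "nest_id",
    "region",
    "year",
    "method",
    "habitat",
    "clutch_class",
    "fate",
    "day_found",
    "day_last_active",
    "day_fate_confirmed",
]

COVARIATE_COLUMNS = [
    "nest_id",
    "day",
    "soil_temp_mean",
    "wind_mean",
    "soil_temp_mean_lag1",
    "wind_mean_lag1",
    "rain",
    "irradiance",
    "day_of_season",
]

#: Numeric weather covariates (unlagged).
WEATHER_VARS = ("soil_temp_mean", "wind_mean", "rain", "irradiance")


class SchemaError(ValueError):
    """A required column is missing or an enum level is unknown."""


class ValidationError(ValueError):
    """A per-row invariant is violated (reported with the nest id)."""


@dataclass(frozen=True)
class NestRecord:
    """One monitored nest with its censored observation triple."""

    nest_id: str
    region: str
    year: int
    method: str
    habitat: str
    clutch_class: str
    fate: str
    day_found: int
    day_last_active: int
    day_fate_confirmed: int

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(f"nest {self.nest_id}: unknown region {self.region!r}")
        if self.method not in METHODS:
            raise ValidationError(f"nest {self.nest_id}: unknown method {self.method!r}")
        if self.habitat not in HABITATS:
            raise ValidationError(f"nest {self.nest_id}: unknown habitat {self.habitat!r}")
        if self.clutch_class not in CLUTCH_CLASSES:
            raise ValidationError(
                f"nest {self.nest_id}: unknown clutch_class {self.clutch_class!r}"
            )
        if self.fate not in FATES:
            raise ValidationError(f"nest {self.nest_id}: unknown fate {self.fate!r}")
        i, j, k = self.day_found, self.day_last_active, self.day_fate_confirmed
        if not (i <= j <= k):
            raise ValidationError(
                f"nest {self.nest_id}: need day_found <= day_last_active <= "
                f"day_fate_confirmed, got ({i}, {j}, {k})"
            )
        if self.fate == "hatched" and j != k:
            raise ValidationError(
                f"nest {self.nest_id}: hatched nests must have "
                f"day_last_active == day_fate_confirmed (got {j}, {k})"
            )
        if self.fate in FAILURE_FATES and j >= k:
            raise ValidationError(
                f"nest {self.nest_id}: failed nests need a nonempty failure window "
                f"day_last_active < day_fate_confirmed (got {j}, {k})"
            )

    @property
    def failed(self) -> bool:
        return self.fate in FAILURE_FATES

    @property
    def included(self) -> bool:
        """Whether the record enters survival fitting and fate tests."""
        return self.fate != "undetermined"


def exposure_days(record: NestRecord) -> tuple[int, int]:
    """Split a nest's observation span into known-alive and failure-window days.

    Returns ``(observed_alive_days, failure_window_days)`` = (j - i, k - j).
    The per-nest exposure tally used in summaries is their sum, k - i: every
    day the nest was under observation and at risk.
    """
    if record.fate == "undetermined":
        raise ValueError(
            f"nest {record.nest_id}: undetermined fate has no exposure contribution"
        )
    return (
        record.day_last_active - record.day_found,
        record.day_fate_confirmed - record.day_last_active,
    )


def records_to_frame(records: Iterable[NestRecord]) -> pd.DataFrame:
    rows = [asdict(r) for r in records]
    if not rows:
        return pd.DataFrame(columns=NEST_COLUMNS)
    return pd.DataFrame(rows, columns=NEST_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[NestRecord]:
    missing = [c for c in NEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"nest table is missing column(s): {', '.join(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            NestRecord(
                nest_id=str(row.nest_id),
                region=str(row.region),
                year=int(row.year),
                method=str(row.method),
                habitat=str(row.habitat),
                clutch_class=str(row.clutch_class),
                fate=str(row.fate),
                day_found=int(row.day_found),
                day_last_active=int(row.day_last_active),
                day_fate_confirmed=int(row.day_fate_confirmed),
            )
        )
    return out


def _looks_like_iso_date(value) -> bool:
    if isinstance(value, str):
        try:
            _dt.date.fromisoformat(value)
            return True
        except ValueError:
            return False
    return False


def read_nest_table(path, season_origin: str | None = None) -> list[NestRecord]:
    """Read a nest encounter-history CSV into validated records.

    Dates may be day-of-season integers or ISO-8601 calendar dates.  Calendar
    dates are mapped to day-of-season with day 1 at ``season_origin`` when
    given, otherwise at the earliest ``day_found`` in the file (the day the
    first nest with eggs was discovered).
    """
    df = pd.read_csv(path, dtype={"nest_id": str})
    missing = [c for c in NEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"nest table is missing column(s): {', '.join(missing)}")
    if len(df) == 0:
        return []
    date_cols = ["day_found", "day_last_active", "day_fate_confirmed"]
    if _looks_like_iso_date(df.loc[df.index[0], "day_found"]):
        for c in date_cols:
            df[c] = pd.to_datetime(df[c], format="%Y-%m-%d")
        if season_origin is not None:
            origin = pd.Timestamp(_dt.date.fromisoformat(season_origin))
        else:
            origin = df["day_found"].min()
        for c in date_cols:
            df[c] = (df[c] - origin).dt.days + 1
    return frame_to_records(df)


def write_nest_table(records: Iterable[NestRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def validate_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Check schema and value invariants of a daily covariate table."""
    missing = [c for c in COVARIATE_COLUMNS if c not in cov.columns]
    if missing:
        raise SchemaError(f"covariate table is missing column(s): {', '.join(missing)}")
    for col in ("rain", "irradiance", "wind_mean"):
        bad = cov[cov[col] < 0]
        if len(bad):
            raise ValidationError(f"negative {col} for nest(s) {sorted(set(bad.nest_id))[:5]}")
    dup = cov.duplicated(subset=["nest_id", "day"])
    if dup.any():
        raise ValidationError(
            f"duplicate (nest_id, day) rows: {cov.loc[dup, ['nest_id', 'day']].values[:5]}"
        )
    return cov


def read_covariate_table(path) -> pd.DataFrame:
    return validate_covariates(pd.read_csv(path, dtype={"nest_id": str}))


def write_covariate_table(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, index=False)


def exposure_summary(
    records: Iterable[NestRecord], by: Sequence[str] = ("region", "method")
) -> pd.DataFrame:
    """Nest counts and exposure-day totals per group (default region x method).

    Exposure days per nest are counted as k - i: all days under observation
    and at risk, including the failure window of failed nests.
    """
    rows = [r for r in records if r.included]
    if not rows:
        return pd.DataFrame(columns=[*by, "n_nests", "exposure_days"])
    df = records_to_frame(rows)
    df["exposure_days"] = df["day_fate_confirmed"] - df["day_found"]
    out = (
        df.groupby(list(by), observed=True)
        .agg(n_nests=("nest_id", "size"), exposure_days=("exposure_days", "sum"))
        .reset_index()
    )
    return out


def join_covariates(
    records: Iterable[NestRecord], covariates: pd.DataFrame
) -> pd.DataFrame:
    """Build the model-ready day-level table.

    One row per included nest per at-risk day t in [i, k), carrying the
    nest's grouping factors, the day's covariates, and ``status``:
    ``"alive"`` for days the nest was confirmed active (t < j) and
    ``"failure_window"`` for days inside the bracketing interval [j, k) of a
    failed nest.  Rows are ordered by (nest_id, day).
    """
    validate_covariates(covariates)
    included = [r for r in records if r.included]
    if not included:
        return pd.DataFrame(
            columns=["nest_id", "day", *NEST_COLUMNS[1:7], "failed", "status",
                     *COVARIATE_COLUMNS[2:]]
        )
    nest_df = records_to_frame(included)
    merged = covariates.merge(
        nest_df.drop(columns=["day_last_active"]).rename(
            columns={"day_found": "_i", "day_fate_confirmed": "_k"}
        ),
        on="nest_id",
        how="inner",
    )
    merged = merged[(merged["day"] >= merged["_i"]) & (merged["day"] < merged["_k"])]

    # every at-risk day must have exactly one covariate row
    counts = merged.groupby("nest_id").size()
    gaps: list[tuple[str, int]] = []
    for r in included:
        expected = r.day_fate_confirmed - r.day_found
        got = int(counts.get(r.nest_id, 0))
        if got != expected:
            have = set(
                merged.loc[merged["nest_id"] == r.nest_id, "day"].astype(int)
            )
            gaps.extend(
                (r.nest_id, d)
                for d in range(r.day_found, r.day_fate_confirmed)
                if d not in have
            )
    if gaps:
        shown = ", ".join(f"({n}, {d})" for n, d in gaps[:10])
        raise ValidationError(
            f"missing covariate rows for {len(gaps)} (nest_id, day) pair(s): {shown}"
        )

    j_map = nest_df.set_index("nest_id")["day_last_active"]
    j_vals = merged["nest_id"].map(j_map)
    merged["failed"] = merged["fate"].isin(FAILURE_FATES)
    merged["status"] = np.where(merged["day"] < j_vals, "alive", "failure_window")
    out_cols = [
        "nest_id", "day", "region", "year", "method", "habitat", "clutch_class",
        "fate", "failed", "status", "soil_temp_mean", "wind_mean",
        "soil_temp_mean_lag1", "wind_mean_lag1", "rain", "irradiance",
        "day_of_season",
    ]
    df = merged[out_cols].copy()
    for col in ("soil_temp_mean", "wind_mean", "soil_temp_mean_lag1",
                "wind_mean_lag1", "rain", "irradiance", "day_of_season"):
        df[col] = df[col].astype(float)
    df["day"] = df["day"].astype(int)
    return df.sort_values(["nest_id", "day"], kind="mergesort").reset_index(drop=True)
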