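"""Data model, time aggregation, alignment, file I/O, and packaged tables.

The campaign data model is deliberately thin: tabular records move through
the pipeline as pandas DataFrames with fixed column contracts rather than
bespoke container classes.

Column contracts
----------------
minute records : ``sensor_id, timestamp, particle_count_hppcf, pm25_ugm3``
hourly records : ``sensor_id, hour_start, pm25, n_minutes``
daily records  : ``sensor_id, date, pm25, n_hours``
sites          : ``site_id, name, community, ej_flag, lat, lon, role``
met            : ``hour_start, temp_c, rh_pct, ws_ms, wd_deg`` (+ derived
                 ``vp_hpa, dew_point_c``)

Hours are labelled by interval start, half-open ``[t, t+1h)``.  An hourly
mean is only reported when at least 75% of the minutes in the hour are
present (>= 45 of 60); the same 75% fraction is applied to days (>= 18 of
24 valid hours).  Negative pollutant values are dropped (not clipped) and
counted in the QC log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger("pmnet")

HOURLY_MIN_MINUTES = 45
DAILY_MIN_HOURS = 18

MINUTE_COLUMNS = ["sensor_id", "timestamp", "particle_count_hppcf", "pm25_ugm3"]
SITE_COLUMNS = ["site_id", "name", "community", "ej_flag", "lat", "lon", "role"]
MET_COLUMNS = ["hour_start", "temp_c", "rh_pct", "ws_ms", "wd_deg"]


class ValidationError(ValueError):
    """Malformed input: bad columns, bad ranges, unresolvable paths."""


class InsufficientDataError(RuntimeError):
    """A statistic was requested on fewer observations than its floor."""


# ---------------------------------------------------------------------------
# study periods


@dataclass(frozen=True)
class StudyPeriods:
    """Three deployment phases as half-open [start, end) intervals.

    ``pre`` and ``post`` are whole-network collocations at a reference
    site; ``deployment`` is the distributed study period.
    """

    pre: tuple[pd.Timestamp, pd.Timestamp]
    deployment: tuple[pd.Timestamp, pd.Timestamp]
    post: tuple[pd.Timestamp, pd.Timestamp]

    def __post_init__(self):
        prev_end = None
        for name in ("pre", "deployment", "post"):
            start, end = (pd.Timestamp(t) for t in getattr(self, name))
            object.__setattr__(self, name, (start, end))
            if not start < end:
                raise ValidationError(f"{name} interval is empty or reversed")
            if prev_end is not None and start < prev_end:
                raise ValidationError("study periods must be ordered and non-overlapping")
            prev_end = end

    @classmethod
    def study_defaults(cls) -> "StudyPeriods":
        """The winter 2016/17 campaign phases: 7-day pre-study collocation,
        two-month deployment, one-month post-study collocation."""
        return cls(
            pre=(pd.Timestamp("2016-11-10"), pd.Timestamp("2016-11-17")),
            deployment=(pd.Timestamp("2016-12-01"), pd.Timestamp("2017-02-01")),
            post=(pd.Timestamp("2017-02-04"), pd.Timestamp("2017-03-08")),
        )

    def hours(self, phase: str) -> pd.DatetimeIndex:
        start, end = getattr(self, phase)
        return pd.date_range(start, end, freq="h", inclusive="left")


# ---------------------------------------------------------------------------
# aggregation


def _drop_negative(df: pd.DataFrame, column: str, what: str) -> pd.DataFrame:
    bad = df[column].notna() & (df[column] < 0)
    if bad.any():
        logger.warning("QC: dropped %d negative %s values", int(bad.sum()), what)
        df = df.copy()
        df.loc[bad, column] = np.nan
    return df


def aggregate_to_hours(
    minutes: pd.DataFrame,
    value: str = "pm25_ugm3",
    min_minutes: int = HOURLY_MIN_MINUTES,
) -> pd.DataFrame:
    """Average minute records to hours with a completeness rule.

    The hourly mean is reported only when at least ``min_minutes`` valid
    minutes fall in the hour (default 45, the 75% rule); the contributing
    minute count ``n_minutes`` is always reported.  Negative pollutant
    values are rejected and QC-logged before averaging.
    """
    if not {"sensor_id", "timestamp", value} <= set(minutes.columns):
        raise ValidationError(f"minute records need sensor_id, timestamp, {value}")
    df = _drop_negative(minutes[["sensor_id", "timestamp", value]], value, "minute PM2.5")
    hour = pd.to_datetime(df["timestamp"]).dt.floor("h")
    grouped = df[value].groupby([df["sensor_id"], hour])
    out = grouped.agg(pm25="mean", n_minutes="count").reset_index()
    out = out.rename(columns={"timestamp": "hour_start"})
    out.loc[out["n_minutes"] < min_minutes, "pm25"] = np.nan
    return out[["sensor_id", "hour_start", "pm25", "n_minutes"]]


def aggregate_to_days(
    hourly: pd.DataFrame,
    min_hours: int = DAILY_MIN_HOURS,
    tz: str | None = None,
) -> pd.DataFrame:
    """Average valid hourly records to calendar days.

    A daily mean is reported only when at least ``min_hours`` of the 24
    hours carry a valid hourly mean (default 18, i.e. the hourly 75%
    fraction applied to days).  ``tz`` shifts day boundaries to a local
    standard time when the input is tz-aware.
    """
    ts = pd.to_datetime(hourly["hour_start"])
    if tz is not None:
        ts = ts.dt.tz_convert(tz)
    date = ts.dt.normalize()
    out = (
        pd.DataFrame({"sensor_id": hourly["sensor_id"], "date": date, "pm25": hourly["pm25"]})
        .groupby(["sensor_id", "date"])["pm25"]
        .agg(pm25="mean", n_hours="count")
        .reset_index()
    )
    # "count" skips NaN, so n_hours is exactly the number of valid hours
    out.loc[out["n_hours"] < min_hours, "pm25"] = np.nan
    return out[["sensor_id", "date", "pm25", "n_hours"]]


def align_pairwise(a: pd.Series, b: pd.Series) -> pd.DataFrame:
    """Inner-join two time-indexed series on timestamps where both are valid.

    Returns a two-column frame (``a``, ``b``) in timestamp order; emits a
    QC warning when the overlap is empty so downstream statistics can
    raise :class:`InsufficientDataError`.
    """
    joined = pd.concat({"a": a, "b": b}, axis=1, join="inner").dropna()
    joined = joined.sort_index()
    if joined.empty:
        logger.warning("QC: pairwise alignment produced zero overlapping records")
    return joined


def to_wide(hourly: pd.DataFrame, value: str = "pm25", index: str = "hour_start") -> pd.DataFrame:
    """Pivot long hourly records to a time x sensor matrix."""
    return hourly.pivot_table(index=index, columns="sensor_id", values=value, aggfunc="first")


# ---------------------------------------------------------------------------
# readers / writers (ISO-8601 timestamps, plain CSV)


def read_sensor_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = {"sensor_id", "timestamp"} - set(df.columns)
    if missing:
        raise ValidationError(f"sensor CSV missing columns: {sorted(missing)}")
    if "pm25_ugm3" not in df.columns and "particle_count_hppcf" not in df.columns:
        raise ValidationError("sensor CSV needs pm25_ugm3 and/or particle_count_hppcf")
    return df


def write_sensor_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def read_sites_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"site CSV missing columns: {sorted(missing)}")
    if ((df["lat"].abs() > 90) | (df["lon"].abs() > 180)).any():
        raise ValidationError("site coordinates outside valid lat/lon ranges")
    if df["community"].isna().any() or (df["community"].astype(str).str.len() == 0).any():
        raise ValidationError("every site needs a community label")
    df["ej_flag"] = df["ej_flag"].astype(bool)
    return df


def read_met_csv(path, enrich: bool = True) -> pd.DataFrame:
    from . import met as _met

    df = pd.read_csv(path, parse_dates=["hour_start"])
    missing = set(MET_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"met CSV missing columns: {sorted(missing)}")
    if ((df["rh_pct"] < 0) | (df["rh_pct"] > 100)).any():
        raise ValidationError("relative humidity outside [0, 100]%")
    if enrich:
        df = _met.enrich_met(df)
    return df


# ---------------------------------------------------------------------------
# packaged printed tables


@dataclass(frozen=True)
class TriangleFixture:
    """A printed site-pair matrix with hourly and daily triangles.

    The published layout stores hourly statistics below the diagonal and
    daily-average statistics above it; both are returned as full
    symmetric matrices (``diagonal`` on the diagonal).
    """

    stat: str
    site_ids: list[str]
    communities: dict[str, str]
    hourly: pd.DataFrame
    daily: pd.DataFrame
    diagonal: float


@dataclass(frozen=True)
class DistanceFixture:
    site_ids: list[str]
    communities: dict[str, str]
    km: pd.DataFrame


def _fixture_path(name: str):
    return resources.files("pmnet.fixtures").joinpath(name)


def _read_matrix_csv(name: str) -> tuple[pd.DataFrame, list[str], dict[str, str]]:
    with resources.as_file(_fixture_path(name)) as p:
        raw = pd.read_csv(p)
    sites = raw["site"].tolist()
    communities = dict(zip(sites, raw["community"]))
    values = raw.drop(columns=["site", "community"]).set_axis(sites, axis=0)
    values.columns = list(values.columns)
    if list(values.columns) != sites:
        raise ValidationError(f"{name}: row and column site labels disagree")
    return values.astype(float), sites, communities


def _mirror(values: pd.DataFrame, triangle: str, diagonal: float) -> pd.DataFrame:
    arr = values.to_numpy(copy=True)
    part = np.tril(np.nan_to_num(arr), k=-1) if triangle == "lower" else np.triu(np.nan_to_num(arr), k=1)
    full = part + part.T + np.eye(len(arr)) * diagonal
    return pd.DataFrame(full, index=values.index, columns=values.columns)


def load_fixture_table(name: str):
    """Load one of the packaged printed tables.

    ``table1``
        per-sensor collocation precision/correction table (DataFrame).
    ``table3``
        site-pair distances in km (:class:`DistanceFixture`).
    ``table4`` / ``table5``
        pairwise R2 / COD matrices (:class:`TriangleFixture`) with the
        hourly lower triangle and daily upper triangle mirrored to full
        symmetric matrices.
    """
    if name == "table1":
        with resources.as_file(_fixture_path("table1.csv")) as p:
            return pd.read_csv(p).set_index("sensor")
    if name == "table3":
        values, sites, communities = _read_matrix_csv("table3.csv")
        return DistanceFixture(sites, communities, _mirror(values, "lower", 0.0))
    if name in ("table4", "table5"):
        stat, diag = ("r2", 1.0) if name == "table4" else ("cod", 0.0)
        values, sites, communities = _read_matrix_csv(f"{name}.csv")
        return TriangleFixture(
            stat=stat,
            site_ids=sites,
            communities=communities,
            hourly=_mirror(values, "lower", diag),
            daily=_mirror(values, "upper", diag),
            diagonal=diag,
        )
    raise ValidationError(f"unknown fixture table: {name!r}")


def lower_triangle(matrix: pd.DataFrame) -> np.ndarray:
    """Off-diagonal values of one triangle of a symmetric site matrix."""
    arr = matrix.to_numpy()
    return arr[np.tril_indices_from(arr, k=-1)]
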