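"""Reading hourly measurement tables and building weekly panels.

Hourly pollutant concentrations are summarised to a weekly time basis: a
station-week is kept only if more than 5 calendar days of that week contain
at least 17 non-missing hourly records each (i.e. >= 6 qualifying days with
the defaults); a kept week is summarised by the arithmetic mean of *all*
non-missing hourly values in the week.  Weeks are ISO-8601 calendar weeks
(Monday-Sunday), identified by the Monday date.

Missing-value conventions for source CSVs: empty cells, non-numeric tokens
("NA", "NULL", ...) and any negative value (networks commonly export negative
sentinels such as -99) are treated as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOURS_PER_WEEK = 168

#: Default weekly-validity thresholds: "more than 5 days with 17-h records or
#: more" == at least 6 days, each with at least 17 hourly values.
MIN_HOURS_PER_DAY = 17
MIN_DAYS_PER_WEEK = 6


@dataclass(frozen=True)
class Station:
    """A geolocated monitoring site."""

    code: str
    lon: float
    lat: float
    pollutants: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"lon out of range for {self.code}: {self.lon}")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"lat out of range for {self.code}: {self.lat}")


@dataclass
class HourlyTable:
    """Hourly records for one pollutant.

    ``frame`` has columns ``station`` (str), ``timestamp`` (datetime64,
    hourly resolution) and ``value`` (float, NaN = missing).
    """

    pollutant: str
    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class WeeklyPanel:
    """Station x week matrix of weekly-mean concentrations.

    ``values``: DataFrame, rows indexed by the Monday of each ISO week
    (consecutive), columns are station codes, NaN marks missing weeks.
    """

    values: pd.DataFrame
    pollutant: str | None = None

    @property
    def stations(self) -> list[str]:
        return list(self.values.columns)

    @property
    def weeks(self) -> pd.DatetimeIndex:
        return self.values.index

    @property
    def n_weeks(self) -> int:
        return len(self.values.index)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="week")

    @classmethod
    def from_csv(cls, path, pollutant: str | None = None) -> "WeeklyPanel":
        values = pd.read_csv(path, index_col="week", parse_dates=["week"])
        return cls(values=values, pollutant=pollutant)


def read_station_catalogue(path) -> pd.DataFrame:
    """Read a station catalogue CSV with columns ``code,lon,lat``.

    Returns a DataFrame indexed by station code with ``lon``/``lat`` columns;
    duplicate codes raise.
    """
    cat = pd.read_csv(path)
    missing = {"code", "lon", "lat"} - set(cat.columns)
    if missing:
        raise ValueError(f"station catalogue missing columns: {sorted(missing)}")
    if cat["code"].duplicated().any():
        dupes = cat.loc[cat["code"].duplicated(), "code"].tolist()
        raise ValueError(f"duplicate station codes in catalogue: {dupes}")
    cat = cat.set_index("code")[["lon", "lat"]].astype(float)
    if (cat["lon"].abs() > 180).any() or (cat["lat"].abs() > 90).any():
        raise ValueError("station coordinates out of WGS84 bounds")
    return cat


def read_measurements(path, pollutant: str) -> HourlyTable:
    """Read an hourly measurements CSV and restrict it to one pollutant.

    Expected columns: ``station,timestamp,pollutant,value`` with ISO-8601
    timestamps.  Unparseable or negative values become missing (NaN).
    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` if the
    pollutant column is absent or a (station, timestamp) appears twice.
    """
    raw = pd.read_csv(path, dtype={"station": str})
    required = {"station", "timestamp", "pollutant", "value"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"measurements file missing columns: {sorted(missing)}")
    raw = raw[raw["pollutant"] == pollutant]
    frame = pd.DataFrame(
        {
            "station": raw["station"].astype(str),
            "timestamp": pd.to_datetime(raw["timestamp"]),
            "value": pd.to_numeric(raw["value"], errors="coerce"),
        }
    ).reset_index(drop=True)
    # negative sentinels (-99 etc.) are missing
    frame.loc[frame["value"] < 0, "value"] = np.nan
    if frame.duplicated(subset=["station", "timestamp"]).any():
        raise ValueError(
            f"duplicate (station, timestamp) records for pollutant {pollutant!r}"
        )
    return HourlyTable(pollutant=pollutant, frame=frame)


def _week_start(ts: pd.Series) -> pd.Series:
    """Monday 00:00 of the ISO week containing each timestamp."""
    days = ts.dt.normalize()
    return days - pd.to_timedelta(ts.dt.dayofweek, unit="D")


def _full_week_index(frame: pd.DataFrame) -> pd.DatetimeIndex:
    ws = _week_start(frame["timestamp"])
    return pd.date_range(ws.min(), ws.max(), freq="7D")


def aggregate_weekly(
    table: HourlyTable,
    min_hours_per_day: int = MIN_HOURS_PER_DAY,
    min_days_per_week: int = MIN_DAYS_PER_WEEK,
) -> WeeklyPanel:
    """Aggregate an hourly table to a weekly panel under the completeness rule.

    A station-week cell is the mean of all non-missing hourly values of that
    ISO week if at least ``min_days_per_week`` calendar days each contain at
    least ``min_hours_per_day`` non-missing hourly records; otherwise the
    cell is missing.  Degenerate weeks simply come out missing; no error is
    raised.
    """
    if min_hours_per_day <= 0 or min_days_per_week <= 0:
        raise ValueError("completeness thresholds must be positive")
    frame = table.frame
    if frame.empty:
        return WeeklyPanel(
            values=pd.DataFrame(index=pd.DatetimeIndex([], name="week")),
            pollutant=table.pollutant,
        )
    work = frame.assign(
        week=_week_start(frame["timestamp"]),
        day=frame["timestamp"].dt.normalize(),
    )
    present = work[work["value"].notna()]
    weeks = _full_week_index(frame)
    stations = sorted(frame["station"].unique())
    values = pd.DataFrame(np.nan, index=weeks, columns=stations)
    values.index.name = "week"
    if not present.empty:
        hours_per_day = present.groupby(["station", "week", "day"]).size()
        qualifying_days = (
            (hours_per_day >= min_hours_per_day).groupby(level=["station", "week"]).sum()
        )
        means = present.groupby(["station", "week"])["value"].mean()
        keep = qualifying_days[qualifying_days >= min_days_per_week].index
        for station, week in keep:
            values.loc[week, station] = means.loc[(station, week)]
    return WeeklyPanel(values=values, pollutant=table.pollutant)


def completeness_matrix(table: HourlyTable) -> pd.DataFrame:
    """Fraction of each station-week's 168 hourly slots that hold a value.

    Rows are ISO-week Mondays, columns station codes, entries in [0, 1].
    Mirrors the tile plots used to visualise monitoring gaps (late station
    activation, outage blocks, permanent shutdowns).
    """
    frame = table.frame
    if frame.empty:
        return pd.DataFrame(index=pd.DatetimeIndex([], name="week"))
    work = frame.assign(week=_week_start(frame["timestamp"]))
    present = work[work["value"].notna()]
    weeks = _full_week_index(frame)
    stations = sorted(frame["station"].unique())
    grid = pd.DataFrame(0.0, index=weeks, columns=stations)
    grid.index.name = "week"
    if not present.empty:
        counts = present.groupby(["week", "station"]).size().unstack(fill_value=0)
        grid.loc[counts.index, counts.columns] = counts / HOURS_PER_WEEK
    return grid
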