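"""Synthetic monitoring networks and spatio-temporal Gaussian random fields.

The generator emulates the data a metropolitan air-quality network produces:
a few dozen stations scattered over a ~60x60 km region, weekly series over
several years whose values are a single realisation of a zero-mean Gaussian
random field with a *known* space-time semivariogram, plus the structured
missingness such networks show (stations that activate late, outage blocks,
permanent shutdowns, scattered dropouts).  Every pipeline stage can thus be
exercised, and parameter recovery judged, without external data.

The field is drawn from the covariance implied by the truth semivariogram,
``C(h, u) = total_sill - gamma(h, u)``, assembled densely over all
station-week cells and Cholesky-factorised; because ``gamma(0,0) = 0``, any
nugget in the truth appears as independent cell-level noise automatically.
For separable truths the covariance is exactly a Kronecker product
``C = sill * C_s (x) C_t``, and the matrix-normal identity
``field = sqrt(sill) * L_s G L_t^T`` gives the same law at a fraction of the
cost; this path makes the 30-station x 200-week recovery studies cheap.

All randomness flows from one integer seed through a ``numpy`` Generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .ingest import HourlyTable, WeeklyPanel
from .empirical import haversine_matrix
from .st_models import SpaceTimeVariogram, evaluate_st, total_sill

#: Dense-covariance ceiling: stations x weeks cells.
MAX_DENSE_CELLS = 20_000

#: Relative diagonal jitter ladder tried before declaring the covariance
#: numerically non-PSD.
JITTER_LADDER = (0.0, 1e-12, 1e-10, 1e-8)

#: Default study region: a ~60x60 km lon/lat box at Mexico City's latitude.
DEFAULT_BBOX = (-99.35, 19.15, -98.78, 19.70)


@dataclass
class MissingnessSpec:
    """Structured missingness: activation, outages, shutdown, random dropout.

    ``activation_week``/``shutdown_week`` map station codes to 0-based week
    positions (cells strictly before activation and at/after shutdown are
    blanked).  ``outages`` is a list of ``(code, start, stop)`` half-open
    week ranges.  ``dropout_rate`` blanks each remaining cell independently.
    """

    activation_week: dict[str, int] = field(default_factory=dict)
    shutdown_week: dict[str, int] = field(default_factory=dict)
    outages: list[tuple[str, int, int]] = field(default_factory=list)
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class SimulationConfig:
    """Full specification of one synthetic study."""

    n_stations: int
    n_weeks: int
    truth: SpaceTimeVariogram
    region: tuple | shapely.Geometry = DEFAULT_BBOX
    measurement_noise: float = 0.0
    missingness: MissingnessSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stations < 2:
            raise ValueError("need at least 2 stations")
        if self.n_weeks < 2:
            raise ValueError("need at least 2 weeks")
        if self.measurement_noise < 0:
            raise ValueError("measurement_noise must be >= 0")


def _region_geometry(region) -> shapely.Geometry:
    if isinstance(region, shapely.Geometry):
        return region
    lon_min, lat_min, lon_max, lat_max = region
    return shapely.box(lon_min, lat_min, lon_max, lat_max)


def generate_network(
    config: SimulationConfig | None = None,
    n_stations: int | None = None,
    region=None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Uniform random station catalogue inside a region.

    Returns a DataFrame indexed by code (``S00``, ``S01``, ...) with
    ``lon``/``lat`` columns; byte-identical across reruns with the same seed.
    """
    if config is not None:
        n_stations, region, seed = config.n_stations, config.region, config.seed
    geom = _region_geometry(region if region is not None else DEFAULT_BBOX)
    if geom.is_empty or geom.area <= 0:
        raise ValueError("degenerate region: zero area")
    rng = np.random.default_rng(seed)
    lon_min, lat_min, lon_max, lat_max = geom.bounds
    lons, lats = [], []
    attempts = 0
    while len(lons) < n_stations:
        attempts += 1
        if attempts > 10_000 * n_stations:
            raise ValueError("region rejection sampling failed; area too thin?")
        lon = rng.uniform(lon_min, lon_max)
        lat = rng.uniform(lat_min, lat_max)
        if geom.contains(shapely.Point(lon, lat)):
            lons.append(lon)
            lats.append(lat)
    codes = [f"S{i:02d}" for i in range(n_stations)]
    return pd.DataFrame({"lon": lons, "lat": lats}, index=pd.Index(codes, name="code"))


def _weekly_index(n_weeks: int, start: str = "2009-01-05") -> pd.DatetimeIndex:
    idx = pd.date_range(start, periods=n_weeks, freq="7D")
    idx.name = "week"
    return idx


def _cholesky_with_jitter(C: np.ndarray, scale: float, truth) -> np.ndarray:
    for jit in JITTER_LADDER:
        try:
            return np.linalg.cholesky(C + jit * scale * np.eye(len(C)))
        except np.linalg.LinAlgError:
            continue
    raise RuntimeError(
        f"covariance not positive semi-definite within jitter budget for "
        f"model {truth.to_config()!r}"
    )


def simulate_field(
    stations: pd.DataFrame,
    n_weeks: int,
    truth: SpaceTimeVariogram,
    seed: int | None = None,
    measurement_noise: float = 0.0,
    start_week: str = "2009-01-05",
) -> WeeklyPanel:
    """One realisation of a zero-mean Gaussian field with semivariogram ``truth``.

    ``measurement_noise`` adds an extra independent nugget (variance units)
    on top of whatever nugget the truth model carries.  Non-separable truths
    use a dense covariance over all station-week cells (limited to
    ~:data:`MAX_DENSE_CELLS`); separable truths use the exact Kronecker
    factorisation.
    """
    S = len(stations)
    T = int(n_weeks)
    rng = np.random.default_rng(seed)
    D = haversine_matrix(stations["lon"].to_numpy(), stations["lat"].to_numpy())

    if truth.structure == "separable":
        # C = sill * (1 - gs_bar(D)) (x) (1 - gt_bar(U)); matrix-normal draw
        lagT = np.abs(np.subtract.outer(np.arange(T), np.arange(T))).astype(float)
        Cs = 1.0 - truth.spatial(D)
        Ct = 1.0 - truth.temporal(lagT)
        Ls = _cholesky_with_jitter(Cs, 1.0, truth)
        Lt = _cholesky_with_jitter(Ct, 1.0, truth)
        G = rng.standard_normal((S, T))
        F = np.sqrt(max(truth.sill, 0.0)) * (Ls @ G @ Lt.T)  # (S, T)
        values = F.T
    else:
        if S * T > MAX_DENSE_CELLS:
            raise ValueError(
                f"{S}x{T} = {S * T} cells exceeds the dense-covariance limit "
                f"({MAX_DENSE_CELLS}); use fewer stations/weeks"
            )
        sill_tot = total_sill(truth)
        Dbig = np.tile(D, (T, T))  # cell order: week-major, station-minor
        lag = np.abs(np.subtract.outer(np.arange(T), np.arange(T))).astype(float)
        Ubig = np.repeat(np.repeat(lag, S, axis=0), S, axis=1)
        C = sill_tot - evaluate_st(truth, Dbig, Ubig)
        L = _cholesky_with_jitter(C, max(sill_tot, 1e-12), truth)
        z = L @ rng.standard_normal(S * T)
        values = z.reshape(T, S)

    if measurement_noise > 0:
        values = values + np.sqrt(measurement_noise) * rng.standard_normal((T, S))

    frame = pd.DataFrame(
        values, index=_weekly_index(T, start_week), columns=stations.index
    )
    return WeeklyPanel(values=frame, pollutant="SYN")


def apply_missingness(
    panel: WeeklyPanel, spec: MissingnessSpec, seed: int | None = None
) -> WeeklyPanel:
    """Blank cells per the missingness spec; other cells are unchanged."""
    values = panel.values.copy()
    T = len(values.index)
    for code, week in spec.activation_week.items():
        if code in values.columns:
            values.iloc[: min(max(week, 0), T), values.columns.get_loc(code)] = np.nan
    for code, week in spec.shutdown_week.items():
        if code in values.columns:
            values.iloc[min(max(week, 0), T):, values.columns.get_loc(code)] = np.nan
    for code, start, stop in spec.outages:
        if code in values.columns:
            values.iloc[
                min(max(start, 0), T): min(max(stop, 0), T),
                values.columns.get_loc(code),
            ] = np.nan
    if spec.dropout_rate > 0:
        rng = np.random.default_rng(seed)
        hit = rng.random(values.shape) < spec.dropout_rate
        values = values.mask(hit)
    return WeeklyPanel(values=values, pollutant=panel.pollutant)


def simulate_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, WeeklyPanel]:
    """Network + field + missingness in one call, all from ``config.seed``."""
    seeds = np.random.SeedSequence(config.seed).generate_state(3) % (2**31)
    catalogue = generate_network(
        n_stations=config.n_stations, region=config.region, seed=int(seeds[0])
    )
    panel = simulate_field(
        catalogue,
        config.n_weeks,
        config.truth,
        seed=int(seeds[1]),
        measurement_noise=config.measurement_noise,
    )
    if config.missingness is not None:
        panel = apply_missingness(panel, config.missingness, seed=int(seeds[2]))
    return catalogue, panel


def panel_to_hourly(panel: WeeklyPanel, pollutant: str | None = None) -> HourlyTable:
    """Expand a weekly panel to hourly records (value constant within a week).

    Every non-missing station-week becomes 168 hourly records carrying the
    weekly value, so re-aggregating through the ingest rules reproduces the
    panel exactly; useful for exercising the real CSV I/O path.
    """
    pollutant = pollutant or panel.pollutant or "SYN"
    hours = pd.timedelta_range("0h", "167h", freq="1h")
    records = []
    for code in panel.values.columns:
        col = panel.values[code].dropna()
        for week, val in col.items():
            records.append(
                pd.DataFrame(
                    {
                        "station": code,
                        "timestamp": week + hours,
                        "value": val,
                    }
                )
            )
    if records:
        frame = pd.concat(records, ignore_index=True)
    else:
        frame = pd.DataFrame(columns=["station", "timestamp", "value"])
    return HourlyTable(pollutant=pollutant, frame=frame)


def write_measurements_csv(table: HourlyTable, path) -> None:
    """Write an hourly table in the CSV dialect the ingest module reads."""
    out = table.frame.assign(pollutant=table.pollutant)[
        ["station", "timestamp", "pollutant", "value"]
    ]
    out.to_csv(path, index=False)
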