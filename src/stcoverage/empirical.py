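"""Empirical (sample) spatio-temporal semivariogram from a weekly panel.

The estimator is the classical method-of-moments one, extended to space-time
lags: for a spatial-distance bin ``j`` and an integer temporal lag ``u``
(in weeks),

    gamma_hat(j, u) = 1 / (2 N) * sum (Z(s_a, t) - Z(s_b, t + u))^2

over every unordered pair of observations whose station separation falls in
bin ``j`` and whose time separation is ``u``; ``N`` is the number of such
pairs (``npairs``).  Pairs involving a missing value are excluded.  For
``u > 0`` and distinct stations both time orderings, (a early, b late) and
(b early, a late), are distinct observation pairs and both contribute.
Same-station pairs (pure temporal lags) land in a dedicated zero-distance
bin.

Station separations are great-circle (haversine) distances in km on a
spherical Earth of radius 6371 km; ranges are therefore directly in km.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import Station, WeeklyPanel

EARTH_RADIUS_KM = 6371.0

#: Default number of equal-width spatial bins spanning (0, max distance].
DEFAULT_N_SPATIAL_BINS = 15


def _coords(obj) -> tuple[float, float]:
    if isinstance(obj, Station):
        return obj.lon, obj.lat
    lon, lat = obj
    return float(lon), float(lat)


def station_distance_km(a, b) -> float:
    """Great-circle distance in km between two stations (or (lon, lat) pairs)."""
    lon1, lat1 = _coords(a)
    lon2, lat2 = _coords(b)
    for lon, lat in ((lon1, lat1), (lon2, lat2)):
        if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
            raise ValueError(f"invalid coordinates lon={lon}, lat={lat}")
    return float(
        haversine_matrix(np.array([lon1, lon2]), np.array([lat1, lat2]))[0, 1]
    )


def haversine_matrix(lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distance matrix (km) for arrays of lon/lat."""
    lam = np.radians(np.asarray(lons, dtype=float))
    phi = np.radians(np.asarray(lats, dtype=float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (
        np.sin(dphi / 2.0) ** 2
        + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2
    )
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class EmpiricalSTVariogram:
    """Binned sample semivariogram on a spatial-bin x temporal-lag grid.

    Row 0 is the zero-distance bin (same-station pairs); rows ``1..B`` are the
    spatial bins ``(edges[i-1], edges[i]]``.  ``dist`` holds the pair-count
    weighted mean separation of each row (0 for the zero bin, the bin midpoint
    where a bin is empty).  ``gamma`` is NaN where ``npairs`` is 0.
    """

    bin_edges: np.ndarray        # (B+1,) increasing from 0
    temporal_lags: np.ndarray    # (U+1,) integer lags 0..U in weeks
    gamma: np.ndarray            # (B+1, U+1)
    npairs: np.ndarray           # (B+1, U+1) integer
    dist: np.ndarray             # (B+1,) representative distance per row, km

    @property
    def n_spatial(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_temporal(self) -> int:
        return self.gamma.shape[1]

    @property
    def max_distance_km(self) -> float:
        return float(self.bin_edges[-1])

    def spatial_marginal(self) -> pd.DataFrame:
        """Pure-spatial sample variogram: the lag-0 column vs distance (rows > 0)."""
        return pd.DataFrame(
            {
                "dist_km": self.dist[1:],
                "gamma": self.gamma[1:, 0],
                "npairs": self.npairs[1:, 0],
            }
        )

    def temporal_marginal(self) -> pd.DataFrame:
        """Pure-temporal sample variogram: the zero-distance row vs lag (lags > 0)."""
        return pd.DataFrame(
            {
                "lag_weeks": self.temporal_lags[1:],
                "gamma": self.gamma[0, 1:],
                "npairs": self.npairs[0, 1:],
            }
        )

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (distance bin, temporal lag) cell."""
        rows, cols = np.meshgrid(
            np.arange(self.n_spatial), np.arange(self.n_temporal), indexing="ij"
        )
        return pd.DataFrame(
            {
                "dist_km": self.dist[rows.ravel()],
                "lag_weeks": self.temporal_lags[cols.ravel()],
                "gamma": self.gamma.ravel(),
                "npairs": self.npairs.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _bin_index_matrix(dist: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Map each pairwise distance to a row index; -1 marks out-of-range."""
    idx = np.digitize(dist, edges[1:], right=True) + 1
    idx[dist == 0.0] = 0
    idx[dist > edges[-1]] = -1
    return idx


def empirical_st_variogram(
    panel: WeeklyPanel,
    catalogue: pd.DataFrame,
    spatial_bins: np.ndarray | None = None,
    n_spatial_bins: int = DEFAULT_N_SPATIAL_BINS,
    max_temporal_lag: int | None = None,
) -> EmpiricalSTVariogram:
    """Compute the binned empirical space-time semivariogram of a weekly panel.

    Parameters
    ----------
    panel : WeeklyPanel
        Weeks x stations matrix with NaN for missing cells.
    catalogue : DataFrame
        Station catalogue indexed by code with ``lon``/``lat`` columns; must
        cover every panel station.
    spatial_bins : array, optional
        Strictly increasing bin edges starting at 0.  Defaults to
        ``n_spatial_bins`` equal-width bins up to the network's maximum
        inter-station distance.
    max_temporal_lag : int, optional
        Largest temporal lag in weeks; defaults to one third of the panel
        length (at least 1).

    Raises ``ValueError`` if fewer than 2 stations or weeks, or if no valid
    pair exists anywhere.
    """
    values = panel.values
    stations = list(values.columns)
    if len(stations) < 2:
        raise ValueError("need at least 2 stations")
    if len(values.index) < 2:
        raise ValueError("need at least 2 weeks")
    missing = [s for s in stations if s not in catalogue.index]
    if missing:
        raise ValueError(f"stations absent from catalogue: {missing}")
    coords = catalogue.loc[stations]
    dist_mat = haversine_matrix(coords["lon"].to_numpy(), coords["lat"].to_numpy())

    if spatial_bins is None:
        max_d = float(dist_mat.max())
        if max_d <= 0:
            raise ValueError("all stations are co-located; cannot bin distances")
        edges = np.linspace(0.0, max_d, n_spatial_bins + 1)
    else:
        edges = np.asarray(spatial_bins, dtype=float)
        if edges[0] != 0 or np.any(np.diff(edges) <= 0):
            raise ValueError("spatial bin edges must strictly increase from 0")
    n_bins = len(edges)  # rows: zero bin + len(edges)-1 interval bins

    T = len(values.index)
    if max_temporal_lag is None:
        max_temporal_lag = max(1, T // 3)
    max_temporal_lag = int(min(max_temporal_lag, T - 1))
    lags = np.arange(max_temporal_lag + 1)

    V = values.to_numpy(dtype=float)  # (T, S)
    S = V.shape[1]
    bin_idx = _bin_index_matrix(dist_mat, edges)

    g_sum = np.zeros((n_bins, len(lags)))
    counts = np.zeros((n_bins, len(lags)), dtype=np.int64)
    dist_wsum = np.zeros(n_bins)
    dist_wcount = np.zeros(n_bins, dtype=np.int64)

    valid = ~np.isnan(V)
    Vz = np.where(valid, V, 0.0)
    iu, ju = np.triu_indices(S, k=1)

    for k, u in enumerate(lags):
        X, Y = Vz[: T - u], Vz[u:]
        MX, MY = valid[: T - u], valid[u:]
        # per station pair (a early, b late): sum of squared diffs and counts
        both = MX.astype(float).T @ MY.astype(float)          # (S, S) pair counts
        sq = (
            (X * X * MX).T @ MY
            + MX.T @ (Y * Y * MY)
            - 2.0 * (X * MX).T @ (Y * MY)
        )
        if u == 0:
            pair_a, pair_b = iu, ju          # unordered station pairs only
            s_ab = sq[iu, ju]
            c_ab = both[iu, ju]
        else:
            # all ordered (a, b) incl. diagonal: each unordered observation
            # pair appears exactly once
            pair_a, pair_b = np.meshgrid(np.arange(S), np.arange(S), indexing="ij")
            pair_a, pair_b = pair_a.ravel(), pair_b.ravel()
            s_ab = sq.ravel()
            c_ab = both.ravel()
        bins = bin_idx[pair_a, pair_b]
        keep = bins >= 0
        bins, s_ab, c_ab = bins[keep], s_ab[keep], c_ab[keep].astype(np.int64)
        g_sum[:, k] += np.bincount(bins, weights=s_ab, minlength=n_bins)
        counts[:, k] += np.bincount(bins, weights=c_ab, minlength=n_bins).astype(
            np.int64
        )
        dist_wsum += np.bincount(
            bins, weights=dist_mat[pair_a, pair_b][keep] * c_ab, minlength=n_bins
        )
        dist_wcount += np.bincount(bins, weights=c_ab, minlength=n_bins).astype(
            np.int64
        )

    if counts.sum() == 0:
        raise ValueError("no valid observation pairs in any (bin, lag) cell")

    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, g_sum / (2.0 * counts), np.nan)

    midpoints = np.concatenate(([0.0], 0.5 * (edges[:-1] + edges[1:])))
    dist = np.where(dist_wcount > 0, dist_wsum / np.maximum(dist_wcount, 1), midpoints)
    dist[0] = 0.0

    return EmpiricalSTVariogram(
        bin_edges=edges,
        temporal_lags=lags,
        gamma=gamma,
        npairs=counts,
        dist=dist,
    )
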