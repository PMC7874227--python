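"""Shared fixtures and independent oracles for the test suite."""

import json

import numpy as np
import pandas as pd
import pytest

from stcoverage import ComponentVariogram, SpaceTimeVariogram, WeeklyPanel

#: ~60x60 km box at Mexico City's latitude, used as the default study region.
BBOX = (-99.35, 19.15, -98.78, 19.70)

DEG_KM_EQUATOR = 6371.0 * np.pi / 180.0  # km per degree of longitude at lat 0


def equator_catalogue(sep_km) -> pd.DataFrame:
    """Stations on the equator at exact km separations (haversine is linear
    in longitude there), for hand-checkable distances."""
    lons = np.concatenate(([0.0], np.cumsum(np.asarray(sep_km)))) / DEG_KM_EQUATOR
    codes = [f"E{i:02d}" for i in range(len(lons))]
    return pd.DataFrame(
        {"lon": lons, "lat": np.zeros_like(lons)},
        index=pd.Index(codes, name="code"),
    )


def make_panel(values, codes=None) -> WeeklyPanel:
    """WeeklyPanel from a (weeks x stations) array; NaN marks missing."""
    values = np.asarray(values, dtype=float)
    codes = codes or [f"E{i:02d}" for i in range(values.shape[1])]
    idx = pd.date_range("2009-01-05", periods=values.shape[0], freq="7D")
    idx.name = "week"
    return WeeklyPanel(values=pd.DataFrame(values, index=idx, columns=codes))


def brute_force_st_variogram(values, dist_mat, edges, max_lag):
    """O(n^2 T^2) all-observation-pairs semivariogram oracle.

    Enumerates every unordered pair of non-missing observations, assigns the
    spatial bin by explicit interval scan (row 0 = zero distance), and
    accumulates squared differences.  Independent of the package's vectorised
    path.
    """
    n_bins = len(edges)
    g = np.zeros((n_bins, max_lag + 1))
    n = np.zeros((n_bins, max_lag + 1), dtype=int)
    T, S = values.shape
    obs = [
        (t, s) for t in range(T) for s in range(S) if not np.isnan(values[t, s])
    ]
    for i in range(len(obs)):
        t1, s1 = obs[i]
        for j in range(i + 1, len(obs)):
            t2, s2 = obs[j]
            u = abs(t1 - t2)
            if u > max_lag:
                continue
            d = dist_mat[s1, s2]
            if d == 0.0:
                b = 0
            else:
                b = -1
                for m in range(len(edges) - 1):
                    if edges[m] < d <= edges[m + 1]:
                        b = m + 1
                        break
                if b < 0:
                    continue
            g[b, u] += (values[t1, s1] - values[t2, s2]) ** 2
            n[b, u] += 1
    gamma = np.where(n > 0, g / (2.0 * np.maximum(n, 1)), np.nan)
    return gamma, n


def separable_truth(
    spatial_range=40.0, temporal_range=8.0, sill=1.0, nugget=0.1
) -> SpaceTimeVariogram:
    """The canonical simulation truth: separable exponential-exponential."""
    return SpaceTimeVariogram(
        "separable",
        spatial=ComponentVariogram("exponential", nugget, 1.0, spatial_range),
        temporal=ComponentVariogram("exponential", nugget, 1.0, temporal_range),
        sill=sill,
    )


def square_region_geojson(path, half_width_deg=0.25, center=(-99.065, 19.425)):
    """Write a simple square study-region polygon as GeoJSON; returns path."""
    cx, cy = center
    ring = [
        [cx - half_width_deg, cy - half_width_deg],
        [cx + half_width_deg, cy - half_width_deg],
        [cx + half_width_deg, cy + half_width_deg],
        [cx - half_width_deg, cy + half_width_deg],
        [cx - half_width_deg, cy - half_width_deg],
    ]
    gj = {
        "type": "Feature",
        "properties": {},
        "geometry": {"type": "Polygon", "coordinates": [ring]},
    }
    path.write_text(json.dumps(gj))
    return path


@pytest.fixture
def bbox():
    return BBOX


@pytest.fixture
def brute_force():
    return brute_force_st_variogram


@pytest.fixture
def region_file(tmp_path):
    return square_region_geojson(tmp_path / "region.geojson")
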