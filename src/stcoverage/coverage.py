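"""Representativeness coverage maps: unions of circles around active stations.

The fitted spatial correlation range of a pollutant is used as a radius: a
circle of that radius around every station active in a given year marks the
zone whose measurements are correlated with the network, and the union of
those circles is the covered area.  Areas and the fraction of a study-region
polygon covered are computed in an azimuthal-equidistant plane (km) centred
on the station centroid — distance-true from the centre and accurate at
metropolitan scale.

Regions are read from GeoJSON (WGS84 lon/lat); coverage polygons can be
written back to GeoJSON in WGS84.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape
from shapely.geometry import mapping as shapely_mapping
from shapely.ops import transform as shapely_transform
from shapely.ops import unary_union

from .empirical import EARTH_RADIUS_KM
from .ingest import WeeklyPanel

#: Circle discretisation for buffers: 64 segments per quadrant keeps the
#: polygonal-area error far below 0.1%.
BUFFER_QUAD_SEGS = 64


class LocalAzimuthalEquidistant:
    """Spherical azimuthal-equidistant projection centred at (lon0, lat0).

    ``forward`` maps lon/lat degrees to (x, y) kilometres; ``inverse`` maps
    back.  Distances from the centre are preserved exactly on the sphere.
    """

    def __init__(self, lon0: float, lat0: float) -> None:
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._lam0 = np.radians(lon0)
        self._phi0 = np.radians(lat0)

    def forward(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        dlam = lam - self._lam0
        cos_c = np.sin(self._phi0) * np.sin(phi) + np.cos(self._phi0) * np.cos(
            phi
        ) * np.cos(dlam)
        c = np.arccos(np.clip(cos_c, -1.0, 1.0))
        # k = c / sin(c), with the limit 1 at the centre
        sin_c = np.sin(c)
        k = np.where(sin_c > 1e-12, c / np.where(sin_c > 1e-12, sin_c, 1.0), 1.0)
        x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(dlam)
        y = EARTH_RADIUS_KM * k * (
            np.cos(self._phi0) * np.sin(phi)
            - np.sin(self._phi0) * np.cos(phi) * np.cos(dlam)
        )
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
        y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
        rho = np.hypot(x, y)
        c = rho
        safe_rho = np.where(rho > 1e-12, rho, 1.0)
        phi = np.arcsin(
            np.clip(
                np.cos(c) * np.sin(self._phi0)
                + y * np.sin(c) * np.cos(self._phi0) / safe_rho,
                -1.0,
                1.0,
            )
        )
        lam = self._lam0 + np.arctan2(
            x * np.sin(c),
            safe_rho * np.cos(self._phi0) * np.cos(c)
            - y * np.sin(self._phi0) * np.sin(c),
        )
        phi = np.where(rho > 1e-12, phi, self._phi0)
        lam = np.where(rho > 1e-12, lam, self._lam0)
        return np.degrees(lam), np.degrees(phi)

    def project_geometry(self, geom):
        """Project a WGS84 shapely geometry into the km plane."""
        return shapely_transform(lambda lon, lat: self.forward(lon, lat), geom)

    def unproject_geometry(self, geom):
        """Map a km-plane shapely geometry back to WGS84 lon/lat."""
        return shapely_transform(lambda x, y: self.inverse(x, y), geom)


def read_region(path):
    """Read a study-region polygon/multipolygon from a GeoJSON file (WGS84).

    Accepts a FeatureCollection (geometries are unioned), a single Feature,
    or a bare geometry object.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [shapely_shape(f["geometry"]) for f in gj["features"]]
        geom = unary_union(geoms)
    elif gj.get("type") == "Feature":
        geom = shapely_shape(gj["geometry"])
    else:
        geom = shapely_shape(gj)
    if geom.is_empty or not geom.is_valid:
        raise ValueError(f"invalid or empty region geometry in {path}")
    return geom


@dataclass
class CoverageMap:
    """Per-pollutant, per-year union-of-circles coverage geometry.

    ``polygon`` lives in the projection's km plane; ``projection`` converts
    it back to WGS84 for GeoJSON export.
    """

    pollutant: str | None
    year: int
    radius_km: float
    stations: tuple[str, ...]
    polygon: shapely.Geometry
    covered_area_km2: float
    region_fraction: float
    projection: LocalAzimuthalEquidistant

    @property
    def n_active(self) -> int:
        return len(self.stations)

    def to_geojson(self) -> dict:
        """The coverage polygon as a WGS84 GeoJSON Feature."""
        geom = self.projection.unproject_geometry(self.polygon)
        return {
            "type": "Feature",
            "properties": {
                "pollutant": self.pollutant,
                "year": self.year,
                "radius_km": self.radius_km,
                "n_active": self.n_active,
                "covered_area_km2": self.covered_area_km2,
                "region_fraction": self.region_fraction,
            },
            "geometry": shapely_mapping(geom),
        }


def active_stations(panel: WeeklyPanel, year: int, min_weeks: int = 1) -> set[str]:
    """Stations with at least ``min_weeks`` non-missing weekly values in a year.

    Weeks are attributed to the calendar year of their ISO-week Monday.
    """
    in_year = panel.values.index.year == year
    counts = panel.values.loc[in_year].notna().sum(axis=0)
    return set(counts.index[counts >= min_weeks])


def buffer_union(
    stations: pd.DataFrame,
    radius_km: float,
    region,
    projection: LocalAzimuthalEquidistant | None = None,
    pollutant: str | None = None,
    year: int = 0,
) -> CoverageMap:
    """Union of circles of ``radius_km`` around stations, vs a region polygon.

    Parameters
    ----------
    stations : DataFrame
        Catalogue slice indexed by code with ``lon``/``lat`` columns; may be
        empty (empty coverage).
    radius_km : float
        Circle radius (> 0) — the fitted spatial correlation range.
    region : shapely geometry
        Study region in WGS84; ``region_fraction`` is the covered share of it.
        Stations outside the region still contribute circles.
    projection : optional
        Plane to buffer in; defaults to an azimuthal-equidistant projection
        centred on the station centroid (or the region centroid if there are
        no stations).
    """
    if not radius_km > 0:
        raise ValueError(f"radius_km must be > 0, got {radius_km}")
    if region.is_empty or not region.is_valid:
        raise ValueError("invalid or empty region polygon")
    if projection is None:
        if len(stations):
            lon0 = float(stations["lon"].mean())
            lat0 = float(stations["lat"].mean())
        else:
            lon0, lat0 = region.centroid.x, region.centroid.y
        projection = LocalAzimuthalEquidistant(lon0, lat0)
    region_proj = projection.project_geometry(region)
    if len(stations):
        x, y = projection.forward(
            stations["lon"].to_numpy(), stations["lat"].to_numpy()
        )
        circles = [
            shapely.Point(xi, yi).buffer(radius_km, quad_segs=BUFFER_QUAD_SEGS)
            for xi, yi in zip(np.atleast_1d(x), np.atleast_1d(y))
        ]
        union = unary_union(circles)
    else:
        union = shapely.Polygon()
    covered = float(union.area)
    frac = float(union.intersection(region_proj).area / region_proj.area)
    return CoverageMap(
        pollutant=pollutant,
        year=year,
        radius_km=float(radius_km),
        stations=tuple(stations.index),
        polygon=union,
        covered_area_km2=covered,
        region_fraction=min(max(frac, 0.0), 1.0),
        projection=projection,
    )


def coverage_timeline(
    panel: WeeklyPanel,
    catalogue: pd.DataFrame,
    radius_km: float,
    region,
    years,
    min_weeks: int = 1,
    pollutant: str | None = None,
) -> list[CoverageMap]:
    """One CoverageMap per year from that year's active stations.

    The same radius (the spatial range fitted on the whole panel) is applied
    to every year; only the active-station set changes.  A single projection
    centred on the full catalogue keeps areas comparable across years.
    """
    pollutant = pollutant or panel.pollutant
    projection = LocalAzimuthalEquidistant(
        float(catalogue["lon"].mean()), float(catalogue["lat"].mean())
    )
    maps = []
    for year in years:
        codes = sorted(active_stations(panel, year, min_weeks=min_weeks))
        sub = catalogue.loc[[c for c in codes if c in catalogue.index]]
        maps.append(
            buffer_union(
                sub,
                radius_km,
                region,
                projection=projection,
                pollutant=pollutant,
                year=int(year),
            )
        )
    return maps


def coverage_summary(maps: list[CoverageMap]) -> pd.DataFrame:
    """Summary table: pollutant, year, n_active, radius, area, region fraction."""
    return pd.DataFrame(
        {
            "pollutant": [m.pollutant for m in maps],
            "year": [m.year for m in maps],
            "n_active": [m.n_active for m in maps],
            "radius_km": [m.radius_km for m in maps],
            "covered_area_km2": [m.covered_area_km2 for m in maps],
            "region_fraction": [m.region_fraction for m in maps],
        }
    )
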