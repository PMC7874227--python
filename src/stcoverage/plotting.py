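"""Quick-look plots: variogram surfaces, completeness tiles, coverage maps.

Matplotlib is an optional dependency; importing this module without it
installed raises a clear error at call time, not import time.
"""

from __future__ import annotations

import numpy as np


def _plt():
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (pip install stcoverage[plot])") from exc
    return plt


def plot_empirical_variogram(emp, ax=None):
    """Heatmap of the empirical semivariogram over (distance, temporal lag)."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots()
    mesh = ax.pcolormesh(
        emp.temporal_lags,
        emp.dist,
        np.ma.masked_invalid(emp.gamma),
        shading="nearest",
    )
    ax.set_xlabel("temporal lag (weeks)")
    ax.set_ylabel("distance (km)")
    ax.figure.colorbar(mesh, ax=ax, label="semivariance")
    return ax


def plot_completeness(grid, ax=None):
    """Tile plot of weekly completeness fractions per station."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 0.25 * max(len(grid.columns), 4) + 1))
    mesh = ax.pcolormesh(
        grid.index, np.arange(len(grid.columns)), grid.T.to_numpy(),
        shading="nearest", vmin=0, vmax=1, cmap="RdYlGn_r",
    )
    ax.set_yticks(np.arange(len(grid.columns)), grid.columns)
    ax.figure.colorbar(mesh, ax=ax, label="completeness")
    return ax


def plot_coverage(cov_map, region=None, ax=None):
    """Coverage polygon (km plane) with station centres and optional region."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots()
    geoms = getattr(cov_map.polygon, "geoms", [cov_map.polygon])
    for geom in geoms:
        if geom.is_empty:
            continue
        x, y = geom.exterior.xy
        ax.fill(x, y, alpha=0.3, color="tab:blue")
    if region is not None:
        reg = cov_map.projection.project_geometry(region)
        for geom in getattr(reg, "geoms", [reg]):
            x, y = geom.exterior.xy
            ax.plot(x, y, color="k", lw=1)
    ax.set_aspect("equal")
    ax.set_title(
        f"{cov_map.pollutant or ''} {cov_map.year}: r={cov_map.radius_km:.1f} km, "
        f"{cov_map.region_fraction:.0%} of region"
    )
    return ax
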