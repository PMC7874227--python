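"""Weighted least-squares fitting of space-time variogram structures.

The entry points mirror the statsmodels idiom: build a
:class:`SpaceTimeVariogramModel` from an empirical variogram, call ``fit()``
to obtain :class:`STVariogramResults` (estimates, weighted mean squared
error, convergence flag, ``summary()``), or run :func:`grid_search` to fit
every structure x component-family candidate and pick the minimum-WMSE one.

Objective
---------
WMSE = sum_c w_c (gamma_hat_c - gamma_model_c)^2 / sum_c w_c over all
non-empty cells c of the empirical grid.  The default weights are
Cressie-style, w_c = npairs_c / gamma_hat_c^2: pair counts scaled down by
the squared semivariance level, which keeps the abundant near-sill cells
from swamping the rising part of the variogram that determines the range.
Plain pair-count weighting is available by passing ``weights=emp.npairs``.
Any uniform rescaling of the weights leaves the objective unchanged.
Parameters are optimised by bound-constrained quasi-Newton (L-BFGS-B) from
a single data-derived initial point.

Initial values
--------------
- nugget guess: median of the means of the first three spatial rows of the
  empirical matrix (temporal guess: first three temporal columns);
- sill guess: median of the means of the last five rows (resp. columns);
- spatial range guess: one third of the largest binned distance;
- temporal range guess: the largest temporal lag;
- spatio-temporal anisotropy (stAni): a least-squares line through matched
  points where the pure-spatial and pure-temporal marginal variograms reach
  the same semivariance level.

Candidate enumeration (75 models): separable and productSum take a spatial
and a temporal family (3 x 3 each), metric a joint family (3), sumMetric and
simpleSumMetric all three (27 each).  Structures enumerate in the order
separable, productSum, metric, sumMetric, simpleSumMetric and families in
the order exponential, spherical, gaussian; ties in WMSE go to the first
candidate in that order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .empirical import EmpiricalSTVariogram
from .st_models import STRUCTURES, SpaceTimeVariogram, evaluate_st
from .variograms import FAMILIES, ComponentVariogram

logger = logging.getLogger(__name__)

#: Which component roles each structure requires, in candidate-id order.
STRUCTURE_ROLES: dict[str, tuple[str, ...]] = {
    "separable": ("spatial", "temporal"),
    "productSum": ("spatial", "temporal"),
    "metric": ("joint",),
    "sumMetric": ("spatial", "temporal", "joint"),
    "simpleSumMetric": ("spatial", "temporal", "joint"),
}


@dataclass(frozen=True)
class InitialParams:
    """Data-derived starting values for the variogram fit.

    ``nugget``/``sill`` come from spatial row means, ``nugget_temporal`` /
    ``sill_temporal`` from temporal column means; ranges are in km and weeks;
    ``st_ani`` is the spatio-temporal anisotropy guess in km/week.
    """

    nugget: float
    sill: float
    spatial_range: float
    temporal_range: float
    st_ani: float
    nugget_temporal: float = 0.0
    sill_temporal: float = 0.0

    def __post_init__(self) -> None:
        if min(self.nugget, self.sill) < 0:
            raise ValueError("nugget and sill guesses must be >= 0")
        if min(self.spatial_range, self.temporal_range, self.st_ani) <= 0:
            raise ValueError("range and anisotropy guesses must be > 0")


def _median_of_edge_means(means: np.ndarray, count: int, first: bool) -> float:
    """Median of the first/last ``count`` finite entries (all if fewer)."""
    finite = means[np.isfinite(means)]
    if finite.size == 0:
        raise ValueError("empirical variogram has no finite cells")
    take = finite[:count] if first else finite[-count:]
    return float(np.median(take))


def initial_guesses(emp: EmpiricalSTVariogram) -> InitialParams:
    """Initial nugget/sill/range/anisotropy values from the empirical grid.

    Nugget = median of the first three spatial-row means, sill = median of
    the last five; the temporal analogues use column means.  Spatial range =
    max binned distance / 3; temporal range = max lag.  When fewer than 3
    rows (or 5) exist, all available ones are used.
    """
    finite = np.isfinite(emp.gamma)
    sums = np.where(finite, emp.gamma, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_means = np.where(
            finite.any(axis=1), sums.sum(axis=1) / finite.sum(axis=1), np.nan
        )
        col_means = np.where(
            finite.any(axis=0), sums.sum(axis=0) / finite.sum(axis=0), np.nan
        )
    nugget = _median_of_edge_means(row_means, 3, first=True)
    sill = _median_of_edge_means(row_means, 5, first=False)
    nugget_t = _median_of_edge_means(col_means, 3, first=True)
    sill_t = _median_of_edge_means(col_means, 5, first=False)
    spatial_range = emp.max_distance_km / 3.0
    temporal_range = float(emp.temporal_lags[-1])
    if spatial_range <= 0 or temporal_range <= 0:
        raise ValueError("degenerate empirical variogram extent")
    init = InitialParams(
        nugget=max(nugget, 0.0),
        sill=max(sill, nugget, 1e-12),
        spatial_range=spatial_range,
        temporal_range=temporal_range,
        st_ani=spatial_range / temporal_range,
        nugget_temporal=max(nugget_t, 0.0),
        sill_temporal=max(sill_t, nugget_t, 0.0),
    )
    try:
        st_ani = estimate_st_anisotropy(emp, _fallback=init.st_ani)
    except ValueError:
        st_ani = init.st_ani
    return InitialParams(
        nugget=init.nugget,
        sill=init.sill,
        spatial_range=init.spatial_range,
        temporal_range=init.temporal_range,
        st_ani=st_ani,
        nugget_temporal=init.nugget_temporal,
        sill_temporal=init.sill_temporal,
    )


def _monotone_curve(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Running-max envelope with strictly increasing y (for level inversion)."""
    order = np.argsort(x)
    x, y = x[order], np.maximum.accumulate(y[order])
    keep = np.concatenate(([True], np.diff(y) > 0))
    return x[keep], y[keep]


def estimate_st_anisotropy(
    emp: EmpiricalSTVariogram, n_levels: int = 9, _fallback: float | None = None
) -> float:
    """Estimate the spatio-temporal anisotropy kappa (km per week).

    Matches semivariance levels between the pure-spatial marginal (lag-0
    column) and the pure-temporal marginal (zero-distance row): for a set of
    common levels, the distances d(level) and lags u(level) are interpolated
    and a least-squares line through the origin, d = kappa * u, gives kappa.
    Flat marginals fall back to spatial-range-guess / temporal-range-guess.
    """
    if _fallback is None:
        _fallback = (emp.max_distance_km / 3.0) / max(float(emp.temporal_lags[-1]), 1.0)

    smarg = emp.spatial_marginal().dropna(subset=["gamma"])
    tmarg = emp.temporal_marginal().dropna(subset=["gamma"])
    if len(smarg) < 2 or len(tmarg) < 2:
        return _fallback
    ds, gs = _monotone_curve(smarg["dist_km"].to_numpy(), smarg["gamma"].to_numpy())
    ut, gt = _monotone_curve(
        tmarg["lag_weeks"].to_numpy(dtype=float), tmarg["gamma"].to_numpy()
    )
    lo = max(gs.min(), gt.min())
    hi = min(gs.max(), gt.max())
    span = max(gs.max() - gs.min(), gt.max() - gt.min())
    if not np.isfinite(span) or span <= 0 or hi <= lo or len(gs) < 2 or len(gt) < 2:
        return _fallback
    levels = lo + (hi - lo) * np.linspace(0.1, 0.9, n_levels)
    d_at = np.interp(levels, gs, ds)
    u_at = np.interp(levels, gt, ut)
    denom = float(np.sum(u_at * u_at))
    if denom <= 0:
        return _fallback
    kappa = float(np.sum(d_at * u_at) / denom)
    if not np.isfinite(kappa) or kappa <= 0:
        return _fallback
    return kappa


# --- parameter vector layouts -------------------------------------------------
# Internally every component is (nugget, partial sill, range) so the bound
# nugget >= 0, psill >= 0 enforces sill >= nugget as a box constraint.


def _param_names(structure: str) -> list[str]:
    if structure == "metric":
        return ["joint_nugget", "joint_psill", "joint_range", "st_ani"]
    if structure == "separable":
        return [
            "sill",
            "spatial_rel_nugget",
            "spatial_range",
            "temporal_rel_nugget",
            "temporal_range",
        ]
    if structure == "productSum":
        return [
            "spatial_nugget", "spatial_psill", "spatial_range",
            "temporal_nugget", "temporal_psill", "temporal_range",
            "k",
        ]
    if structure == "sumMetric":
        return [
            "spatial_nugget", "spatial_psill", "spatial_range",
            "temporal_nugget", "temporal_psill", "temporal_range",
            "joint_nugget", "joint_psill", "joint_range",
            "st_ani",
        ]
    if structure == "simpleSumMetric":
        return [
            "nugget",
            "spatial_psill", "spatial_range",
            "temporal_psill", "temporal_range",
            "joint_psill", "joint_range",
            "st_ani",
        ]
    raise ValueError(f"unknown structure {structure!r}")


def _build_model(
    structure: str, families: dict[str, str], theta: np.ndarray
) -> SpaceTimeVariogram:
    p = dict(zip(_param_names(structure), theta))
    comp = ComponentVariogram
    if structure == "metric":
        return SpaceTimeVariogram(
            "metric",
            joint=comp(
                families["joint"],
                p["joint_nugget"],
                p["joint_nugget"] + p["joint_psill"],
                p["joint_range"],
            ),
            st_ani=p["st_ani"],
        )
    if structure == "separable":
        return SpaceTimeVariogram(
            "separable",
            spatial=comp(families["spatial"], p["spatial_rel_nugget"], 1.0,
                         p["spatial_range"]),
            temporal=comp(families["temporal"], p["temporal_rel_nugget"], 1.0,
                          p["temporal_range"]),
            sill=p["sill"],
        )
    if structure == "productSum":
        return SpaceTimeVariogram(
            "productSum",
            spatial=comp(families["spatial"], p["spatial_nugget"],
                         p["spatial_nugget"] + p["spatial_psill"],
                         p["spatial_range"]),
            temporal=comp(families["temporal"], p["temporal_nugget"],
                          p["temporal_nugget"] + p["temporal_psill"],
                          p["temporal_range"]),
            k=p["k"],
        )
    if structure == "sumMetric":
        return SpaceTimeVariogram(
            "sumMetric",
            spatial=comp(families["spatial"], p["spatial_nugget"],
                         p["spatial_nugget"] + p["spatial_psill"],
                         p["spatial_range"]),
            temporal=comp(families["temporal"], p["temporal_nugget"],
                          p["temporal_nugget"] + p["temporal_psill"],
                          p["temporal_range"]),
            joint=comp(families["joint"], p["joint_nugget"],
                       p["joint_nugget"] + p["joint_psill"], p["joint_range"]),
            st_ani=p["st_ani"],
        )
    # simpleSumMetric
    return SpaceTimeVariogram(
        "simpleSumMetric",
        spatial=comp(families["spatial"], 0.0, p["spatial_psill"],
                     p["spatial_range"]),
        temporal=comp(families["temporal"], 0.0, p["temporal_psill"],
                      p["temporal_range"]),
        joint=comp(families["joint"], 0.0, p["joint_psill"], p["joint_range"]),
        st_ani=p["st_ani"],
        nugget=p["nugget"],
    )


def _initial_vector(
    structure: str, init: InitialParams, gmax: float
) -> np.ndarray:
    n, s = init.nugget, max(init.sill, init.nugget)
    psill = max(s - n, 1e-8 * max(gmax, 1.0))
    rs, rt, kappa = init.spatial_range, init.temporal_range, init.st_ani
    nt = init.nugget_temporal
    st = max(init.sill_temporal, nt)
    if structure == "metric":
        return np.array([n, psill, rs, kappa])
    if structure == "separable":
        rel = min(n / s, 0.9) if s > 0 else 0.0
        rel_t = min(nt / st, 0.9) if st > 0 else rel
        return np.array([s, rel, rs, rel_t, rt])
    if structure == "productSum":
        # split the total variance evenly; small initial coupling
        k0 = 1.0 / max(s, 1e-8)
        return np.array([n / 2, psill / 2, rs, nt / 2, max(st - nt, psill / 2) / 2,
                         rt, k0])
    if structure == "sumMetric":
        return np.array([
            n / 3, psill / 3, rs,
            n / 3, psill / 3, rt,
            n / 3, psill / 3, rs,
            kappa,
        ])
    # simpleSumMetric
    return np.array([n, psill / 3, rs, psill / 3, rt, psill / 3, rs, kappa])


def _bounds(
    structure: str, init: InitialParams, gmax: float, max_dist: float, max_lag: float
) -> list[tuple[float, float]]:
    vmax = 10.0 * max(gmax, 1e-8)
    r_s = (1e-3 * max_dist, 10.0 * max_dist)
    r_t = (max(1e-3 * max_lag, 1e-3), 10.0 * max_lag)
    kappa_b = (init.st_ani / 100.0, init.st_ani * 100.0)
    names = _param_names(structure)
    out: list[tuple[float, float]] = []
    for name in names:
        if name.endswith("rel_nugget"):
            out.append((0.0, 1.0 - 1e-9))
        elif name in ("sill",) or name.endswith(("nugget", "psill")):
            out.append((0.0, vmax))
        elif name == "spatial_range" or name == "joint_range":
            out.append(r_s)
        elif name == "temporal_range":
            out.append(r_t)
        elif name == "k":
            out.append((1e-8, 1e4 / max(gmax, 1e-8)))
        elif name == "st_ani":
            out.append(kappa_b)
        else:  # pragma: no cover
            raise AssertionError(name)
    return out


def _candidate_id(structure: str, families: dict[str, str]) -> str:
    parts = [families[r] for r in STRUCTURE_ROLES[structure]]
    return f"{structure}:" + "+".join(parts)


class SpaceTimeVariogramModel:
    """Weighted least-squares fit of one space-time structure to an
    empirical variogram.

    Parameters
    ----------
    emp : EmpiricalSTVariogram
        The fitting target; cells with ``npairs == 0`` are ignored.
    structure : str
        One of the five structures (see :mod:`stcoverage.st_models`).
    families : mapping or sequence
        Component families per role.  A mapping like
        ``{"spatial": "exponential", "temporal": "spherical"}`` or a sequence
        in the structure's role order (spatial, temporal, joint as
        applicable).
    init : InitialParams, optional
        Starting values; derived from ``emp`` when omitted.
    weights : array, optional
        Per-cell weights on the empirical grid; defaults to pair counts.
    """

    def __init__(
        self,
        emp: EmpiricalSTVariogram,
        structure: str,
        families,
        init: InitialParams | None = None,
        weights: np.ndarray | None = None,
    ) -> None:
        if structure not in STRUCTURES:
            raise ValueError(
                f"unknown structure {structure!r}; expected one of {STRUCTURES}"
            )
        roles = STRUCTURE_ROLES[structure]
        if not isinstance(families, dict):
            families = dict(zip(roles, families))
        missing = [r for r in roles if r not in families]
        if missing:
            raise ValueError(f"structure {structure!r} needs families for {missing}")
        for role in roles:
            if families[role] not in FAMILIES:
                raise ValueError(f"unknown family {families[role]!r} for {role}")
        self.emp = emp
        self.structure = structure
        self.families = {r: families[r] for r in roles}
        self.init = init if init is not None else initial_guesses(emp)

        if weights is None:
            # Cressie-style WLS: pair counts down-weighted by the squared
            # semivariance level, emphasising the rising (range-determining)
            # part of the variogram over the many near-sill cells.  A small
            # floor keeps near-zero-lag cells from dominating.
            w = emp.npairs.astype(float)
            gabs = np.abs(emp.gamma)
            gmax = float(np.nanmax(gabs)) if np.isfinite(gabs).any() else 0.0
            if gmax > 0:
                w = w / np.maximum(gabs, 1e-3 * gmax) ** 2
        else:
            w = np.asarray(weights, float)
        mask = (w > 0) & np.isfinite(emp.gamma)
        if not mask.any():
            raise ValueError("no usable cells in the empirical variogram")
        self._mask = mask
        self._w = w[mask] / w[mask].sum()
        self._g = emp.gamma[mask]
        H = np.broadcast_to(emp.dist[:, None], emp.gamma.shape)
        U = np.broadcast_to(
            emp.temporal_lags[None, :].astype(float), emp.gamma.shape
        )
        self._h = H[mask]
        self._u = U[mask]
        self._gmax = float(np.nanmax(np.abs(self._g))) or 1.0

    @property
    def candidate_id(self) -> str:
        return _candidate_id(self.structure, self.families)

    def wmse(self, model: SpaceTimeVariogram) -> float:
        """Weighted mean squared error of an arbitrary model on this grid."""
        resid = evaluate_st(model, self._h, self._u) - self._g
        return float(np.sum(self._w * resid * resid))

    def _objective(self, theta: np.ndarray) -> float:
        try:
            model = _build_model(self.structure, self.families, theta)
        except ValueError:
            return 1e12
        return self.wmse(model) / (self._gmax**2)

    def fit(self, maxiter: int = 500, tol: float = 1e-8) -> "STVariogramResults":
        """Minimise the WMSE by L-BFGS-B from the data-derived start.

        Returns results even on optimizer failure (``converged=False`` with
        the best iterate found).
        """
        theta0 = _initial_vector(self.structure, self.init, self._gmax)
        bounds = _bounds(
            self.structure,
            self.init,
            self._gmax,
            self.emp.max_distance_km,
            float(self.emp.temporal_lags[-1]),
        )
        theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])
        options = {"maxiter": maxiter, "ftol": min(tol * 1e-4, 1e-15),
                   "gtol": 1e-14, "maxfun": 100_000}
        res = minimize(
            self._objective, theta0, method="L-BFGS-B", bounds=bounds,
            options=options,
        )
        # warm restart: resetting the quasi-Newton memory at the incumbent
        # reliably polishes stalls on near-flat parameter trade-offs
        res2 = minimize(
            self._objective, res.x, method="L-BFGS-B", bounds=bounds,
            options=options,
        )
        if res2.fun <= res.fun:
            res = res2
        theta = np.asarray(res.x, dtype=float)
        model = _build_model(self.structure, self.families, theta)
        return STVariogramResults(
            model=model,
            params=dict(zip(_param_names(self.structure), theta)),
            wmse=self.wmse(model),
            converged=bool(res.success),
            candidate_id=self.candidate_id,
            n_cells=int(self._mask.sum()),
            message=str(res.message),
            init=self.init,
            _fit_parent=self,
        )


@dataclass
class STVariogramResults:
    """Results of a space-time variogram fit."""

    model: SpaceTimeVariogram
    params: dict[str, float]
    wmse: float
    converged: bool
    candidate_id: str
    n_cells: int
    message: str = ""
    init: InitialParams | None = None
    _fit_parent: SpaceTimeVariogramModel | None = field(default=None, repr=False)

    @property
    def structure(self) -> str:
        return self.model.structure

    @property
    def spatial_range_km(self) -> float:
        """The fitted spatial correlation range (km): the spatial component's
        range, or the joint range for the pure metric structure."""
        if self.model.spatial is not None:
            return float(self.model.spatial.range)
        return float(self.model.joint.range)

    @property
    def temporal_range_weeks(self) -> float:
        """The fitted temporal correlation range (weeks): the temporal
        component's range, or joint range / stAni for the metric structure."""
        if self.model.temporal is not None:
            return float(self.model.temporal.range)
        return float(self.model.joint.range / self.model.st_ani)

    def predict(self, h, u):
        """Model semivariance gamma(h, u)."""
        return evaluate_st(self.model, h, u)

    def summary(self) -> str:
        """Plain-text summary table of the fitted model."""
        lines = [
            "Space-time variogram fit",
            "=" * 40,
            f"candidate        {self.candidate_id}",
            f"n cells          {self.n_cells}",
            f"WMSE             {self.wmse:.6g}",
            f"converged        {self.converged}",
            f"spatial range    {self.spatial_range_km:.4g} km",
            f"temporal range   {self.temporal_range_weeks:.4g} weeks",
            "-" * 40,
        ]
        for name, val in self.params.items():
            lines.append(f"{name:<22s} {val:.6g}")
        return "\n".join(lines)


def fit_st_model(
    emp: EmpiricalSTVariogram,
    structure: str,
    families,
    init: InitialParams | None = None,
    **fit_kwargs,
) -> STVariogramResults:
    """Functional wrapper: build a model and fit it in one call."""
    return SpaceTimeVariogramModel(emp, structure, families, init=init).fit(
        **fit_kwargs
    )


def enumerate_candidates() -> list[tuple[str, dict[str, str]]]:
    """All 75 structure x family-assignment candidates in canonical order."""
    out = []
    for structure in STRUCTURES:
        roles = STRUCTURE_ROLES[structure]
        for combo in itertools.product(FAMILIES, repeat=len(roles)):
            out.append((structure, dict(zip(roles, combo))))
    return out


@dataclass
class GridSearchResult:
    """Winner and full leaderboard of the exhaustive candidate search."""

    winner: STVariogramResults
    results: list[STVariogramResults]
    failures: dict[str, str]

    @property
    def leaderboard(self) -> pd.DataFrame:
        """One row per candidate: structure, families, WMSE and parameters,
        sorted by WMSE (stable, so ties keep enumeration order)."""
        rows = []
        for res in self.results:
            row: dict = {
                "candidate_id": res.candidate_id,
                "structure": res.structure,
                "spatial_family": None,
                "temporal_family": None,
                "joint_family": None,
                "wmse": res.wmse,
                "converged": res.converged,
                "spatial_range_km": res.spatial_range_km,
                "temporal_range_weeks": res.temporal_range_weeks,
            }
            for role in ("spatial", "temporal", "joint"):
                comp = getattr(res.model, role)
                if comp is not None:
                    row[f"{role}_family"] = comp.family
            row.update(res.params)
            rows.append(row)
        frame = pd.DataFrame(rows)
        return frame.sort_values("wmse", kind="stable").reset_index(drop=True)


def grid_search(
    emp: EmpiricalSTVariogram,
    init: InitialParams | None = None,
    **fit_kwargs,
) -> GridSearchResult:
    """Fit all 75 candidates and return the minimum-WMSE winner.

    Candidates whose optimisation raises are recorded in ``failures`` and
    excluded from the leaderboard; if every candidate fails, a ``ValueError``
    listing the per-candidate errors is raised.
    """
    if init is None:
        init = initial_guesses(emp)
    results: list[STVariogramResults] = []
    failures: dict[str, str] = {}
    candidates = enumerate_candidates()
    for i, (structure, families) in enumerate(candidates):
        cid = _candidate_id(structure, families)
        try:
            res = SpaceTimeVariogramModel(emp, structure, families, init=init).fit(
                **fit_kwargs
            )
        except Exception as exc:  # noqa: BLE001 - per-candidate isolation
            failures[cid] = f"{type(exc).__name__}: {exc}"
            logger.warning("candidate %s failed: %s", cid, exc)
            continue
        logger.debug(
            "candidate %d/%d %s: wmse=%.6g", i + 1, len(candidates), cid, res.wmse
        )
        results.append(res)
    if not results:
        raise ValueError(f"all candidates failed: {failures}")
    winner = min(results, key=lambda r: r.wmse)  # stable: first minimal wins
    logger.info("grid search winner %s (wmse=%.6g)", winner.candidate_id, winner.wmse)
    return GridSearchResult(winner=winner, results=results, failures=failures)
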