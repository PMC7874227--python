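"""Space-time semivariogram structures gamma(h, u).

Five standard ways of composing component semivariograms into a space-time
model, following the gstat naming:

separable
    ``gamma(h,u) = sill * (gs(h) + gt(u) - gs(h)*gt(u))`` with *standardized*
    spatial/temporal components (sill 1, separate nuggets) and one overall
    sill.
productSum
    ``gamma(h,u) = (k*sill_t + 1)*gs(h) + (k*sill_s + 1)*gt(u) - k*gs(h)*gt(u)``
    with unstandardized components and a positive coupling ``k``; the joint
    sill obeys the identity ``sill_st = k*sill_s*sill_t + sill_s + sill_t``.
metric
    ``gamma(h,u) = g_joint(sqrt(h^2 + (kappa*u)^2))``, a single joint
    component on the metric that equates one time unit with ``kappa``
    space units (the spatio-temporal anisotropy, "stAni").
sumMetric
    ``gamma(h,u) = gs(h) + gt(u) + g_joint(sqrt(h^2 + (kappa*u)^2))``.
simpleSumMetric
    sumMetric restricted to nugget-free components plus one overall nugget
    applied whenever ``(h,u) != (0,0)``.

Every structure satisfies ``gamma(0, 0) = 0``.

The joint-component argument is ``sqrt(h^2 + (kappa*u)^2)`` for all three
metric-type structures, i.e. kappa rescales the temporal lag before the
Euclidean mix; this keeps the metric dimensionally consistent (km vs weeks)
and matches the gstat reference convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .variograms import ComponentVariogram

#: Supported structures, in canonical enumeration order.
STRUCTURES = ("separable", "productSum", "metric", "sumMetric", "simpleSumMetric")


def product_sum_sill(k: float, sill_s: float, sill_t: float) -> float:
    """Joint sill of the productSum structure: k*sill_s*sill_t + sill_s + sill_t.

    Raises ``ValueError`` if ``k <= 0``.
    """
    if not k > 0:
        raise ValueError(f"productSum coupling k must be > 0, got {k}")
    return k * sill_s * sill_t + sill_s + sill_t


@dataclass
class SpaceTimeVariogram:
    """A composed space-time semivariogram model.

    Which fields are required depends on ``structure``:

    - ``separable``: ``spatial``, ``temporal`` (stored standardized to sill 1;
      arbitrary components are rescaled on construction), ``sill``.
    - ``productSum``: ``spatial``, ``temporal`` (unstandardized), ``k > 0``.
    - ``metric``: ``joint``, ``st_ani > 0``.
    - ``sumMetric``: ``spatial``, ``temporal``, ``joint``, ``st_ani > 0``.
    - ``simpleSumMetric``: nugget-free ``spatial``, ``temporal``, ``joint``,
      one overall ``nugget``, ``st_ani > 0``.

    ``st_ani`` (kappa) is the spatio-temporal anisotropy in space units per
    time unit (here km/week).
    """

    structure: str
    spatial: ComponentVariogram | None = None
    temporal: ComponentVariogram | None = None
    joint: ComponentVariogram | None = None
    sill: float | None = None
    k: float | None = None
    st_ani: float | None = None
    nugget: float | None = None

    def __post_init__(self) -> None:
        s = self.structure
        if s not in STRUCTURES:
            raise ValueError(f"unknown structure {s!r}; expected one of {STRUCTURES}")
        if s == "separable":
            self._require(spatial=True, temporal=True)
            if self.sill is None or not self.sill >= 0:
                raise ValueError("separable requires an overall sill >= 0")
            self.spatial = self.spatial.standardized()
            self.temporal = self.temporal.standardized()
        elif s == "productSum":
            self._require(spatial=True, temporal=True)
            if self.k is None or not self.k > 0:
                raise ValueError("productSum requires coupling k > 0")
        elif s == "metric":
            self._require(joint=True)
            self._require_stani()
        elif s == "sumMetric":
            self._require(spatial=True, temporal=True, joint=True)
            self._require_stani()
        elif s == "simpleSumMetric":
            self._require(spatial=True, temporal=True, joint=True)
            self._require_stani()
            if self.nugget is None or not self.nugget >= 0:
                raise ValueError("simpleSumMetric requires a single nugget >= 0")
            for name in ("spatial", "temporal", "joint"):
                comp = getattr(self, name)
                if comp.nugget != 0:
                    raise ValueError(
                        f"simpleSumMetric {name} component must have zero nugget"
                    )

    def _require(self, spatial=False, temporal=False, joint=False) -> None:
        for name, needed in (
            ("spatial", spatial), ("temporal", temporal), ("joint", joint)
        ):
            if needed and getattr(self, name) is None:
                raise ValueError(
                    f"structure {self.structure!r} requires a {name} component"
                )

    def _require_stani(self) -> None:
        if self.st_ani is None or not self.st_ani > 0:
            raise ValueError(
                f"structure {self.structure!r} requires st_ani (kappa) > 0"
            )

    def __call__(self, h, u):
        return evaluate_st(self, h, u)

    def to_config(self) -> dict:
        cfg: dict = {"structure": self.structure}
        for name in ("spatial", "temporal", "joint"):
            comp = getattr(self, name)
            if comp is not None:
                for key, val in comp.to_config().items():
                    cfg[f"{name}_{key}"] = val
        for key in ("sill", "k", "st_ani", "nugget"):
            val = getattr(self, key)
            if val is not None:
                cfg[key] = val
        return cfg

    @classmethod
    def from_config(cls, cfg: dict) -> "SpaceTimeVariogram":
        kwargs: dict = {"structure": cfg["structure"]}
        for name in ("spatial", "temporal", "joint"):
            if f"{name}_family" in cfg:
                kwargs[name] = ComponentVariogram(
                    cfg[f"{name}_family"],
                    cfg[f"{name}_nugget"],
                    cfg[f"{name}_sill"],
                    cfg[f"{name}_range"],
                )
        for key in ("sill", "k", "st_ani", "nugget"):
            if key in cfg and cfg[key] is not None:
                kwargs[key] = cfg[key]
        return cls(**kwargs)


def _joint_lag(h: np.ndarray, u: np.ndarray, kappa: float) -> np.ndarray:
    return np.sqrt(h * h + (kappa * u) ** 2)


def evaluate_st(model: SpaceTimeVariogram, h, u) -> np.ndarray | float:
    """Evaluate gamma(h, u) for spatial lag h >= 0 and temporal lag u >= 0.

    ``h`` and ``u`` broadcast against each other; gamma(0, 0) = 0 for every
    structure.
    """
    harr = np.asarray(h, dtype=float)
    uarr = np.asarray(u, dtype=float)
    if np.any(harr < 0) or np.any(uarr < 0):
        raise ValueError("lags h and u must be >= 0")
    harr, uarr = np.broadcast_arrays(harr, uarr)
    s = model.structure
    if s == "separable":
        gs = model.spatial(harr)
        gt = model.temporal(uarr)
        gamma = model.sill * (gs + gt - gs * gt)
    elif s == "productSum":
        gs = model.spatial(harr)
        gt = model.temporal(uarr)
        ss, st = model.spatial.sill, model.temporal.sill
        k = model.k
        gamma = (k * st + 1.0) * gs + (k * ss + 1.0) * gt - k * gs * gt
    elif s == "metric":
        gamma = model.joint(_joint_lag(harr, uarr, model.st_ani))
    elif s == "sumMetric":
        gamma = (
            model.spatial(harr)
            + model.temporal(uarr)
            + model.joint(_joint_lag(harr, uarr, model.st_ani))
        )
    else:  # simpleSumMetric
        step = ((harr > 0) | (uarr > 0)).astype(float)
        gamma = (
            model.nugget * step
            + model.spatial(harr)
            + model.temporal(uarr)
            + model.joint(_joint_lag(harr, uarr, model.st_ani))
        )
    if np.isscalar(h) and np.isscalar(u):
        return float(gamma)
    return np.asarray(gamma)


def total_sill(model: SpaceTimeVariogram) -> float:
    """Asymptotic sill of gamma(h, u) as both lags grow without bound."""
    s = model.structure
    if s == "separable":
        return float(model.sill)
    if s == "productSum":
        return product_sum_sill(model.k, model.spatial.sill, model.temporal.sill)
    if s == "metric":
        return float(model.joint.sill)
    if s == "sumMetric":
        return float(model.spatial.sill + model.temporal.sill + model.joint.sill)
    # simpleSumMetric
    return float(
        model.nugget + model.spatial.sill + model.temporal.sill + model.joint.sill
    )


def covariance_st(model: SpaceTimeVariogram, h, u) -> np.ndarray | float:
    """Space-time covariance C(h, u) = total_sill - gamma(h, u).

    Internal helper for the Gaussian-field simulator; C(0,0) equals the total
    sill, and the nugget appears as an independent-noise jump on the diagonal.
    """
    return total_sill(model) - evaluate_st(model, h, u)
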