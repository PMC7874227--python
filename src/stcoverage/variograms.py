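"""Component semivariogram families: exponential, spherical and Gaussian.

Each family is parameterised by a nugget ``n`` (the right-limit of the
semivariogram at zero lag, capturing micro-scale variation and measurement
error), a sill ``s`` (the limiting semivariance at large lag, with ``s >= n``)
and a range ``r`` (the lag at which correlation is effectively lost).

For the asymptotic families (exponential, Gaussian) the range is tied to the
"95% of the sill" practical-range convention through the fixed scale constant
``a = 1/3``: at ``h = r`` both families attain ``n + (1 - e^-3)(s - n)``,
i.e. ~95.02% of the partial sill above the nugget.  The spherical family
reaches the sill exactly at ``h = r``.

All families evaluate to exactly 0 at zero lag (the nugget enters through a
Heaviside step that excludes the origin), so the semivariogram of a pair of
identical points is well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Practical-range scale constant `a`; makes `r` the 95%-of-sill distance
#: for the exponential and Gaussian families.
PRACTICAL_RANGE_SCALE = 1.0 / 3.0

#: Supported component families, in canonical enumeration order.
FAMILIES = ("exponential", "spherical", "gaussian")


@dataclass(frozen=True)
class ComponentVariogram:
    """A single-component semivariogram model gamma(h).

    Parameters
    ----------
    family : str
        One of ``"exponential"``, ``"spherical"``, ``"gaussian"``.
    nugget : float
        Semivariance right-limit at zero lag, >= 0.
    sill : float
        Limiting semivariance at large lag, >= nugget.
    range : float
        Correlation range in lag units, > 0.
    """

    family: str
    nugget: float
    sill: float
    range: float
    a: float = field(default=PRACTICAL_RANGE_SCALE, repr=False)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if not self.nugget >= 0:
            raise ValueError(f"nugget must be >= 0, got {self.nugget}")
        if not self.sill >= self.nugget:
            raise ValueError(
                f"sill ({self.sill}) must be >= nugget ({self.nugget})"
            )
        if not self.range > 0:
            raise ValueError(f"range must be > 0, got {self.range}")
        if self.a != PRACTICAL_RANGE_SCALE:
            raise ValueError("the practical-range constant a is fixed at 1/3")

    def __call__(self, h):
        return evaluate(self, h)

    def standardized(self) -> "ComponentVariogram":
        """Return a copy rescaled to sill 1 (nugget scaled proportionally)."""
        if self.sill <= 0:
            # degenerate pure-zero component; keep shape, unit sill
            return ComponentVariogram(self.family, 0.0, 1.0, self.range)
        return ComponentVariogram(
            self.family, self.nugget / self.sill, 1.0, self.range
        )

    def to_config(self) -> dict:
        return {
            "family": self.family,
            "nugget": self.nugget,
            "sill": self.sill,
            "range": self.range,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "ComponentVariogram":
        return cls(cfg["family"], cfg["nugget"], cfg["sill"], cfg["range"])


def _shape(family: str, h: np.ndarray, r: float) -> np.ndarray:
    """Normalised shape in [0, 1]: the semivariogram with nugget 0, sill 1."""
    if family == "exponential":
        return 1.0 - np.exp(-h / (r * PRACTICAL_RANGE_SCALE))
    if family == "gaussian":
        return 1.0 - np.exp(-(h * h) / (r * r * PRACTICAL_RANGE_SCALE))
    # spherical: polynomial up to the range, 1 beyond
    hr = np.minimum(h / r, 1.0)
    return 1.5 * hr - 0.5 * hr**3


def evaluate(model: ComponentVariogram, h) -> np.ndarray | float:
    """Evaluate gamma(h) for lags h >= 0.

    gamma(0) = 0 exactly; the right-limit at 0+ is the nugget.  Raises
    ``ValueError`` for negative lags.
    """
    harr = np.asarray(h, dtype=float)
    if np.any(harr < 0):
        raise ValueError("lag h must be >= 0")
    n, s = model.nugget, model.sill
    gamma = np.where(
        harr > 0, n + (s - n) * _shape(model.family, harr, model.range), 0.0
    )
    if np.isscalar(h) or harr.ndim == 0:
        return float(gamma)
    return gamma
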