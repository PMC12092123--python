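"""Allometric scaling: length-to-mass conversion and log-log slope fits.

Spider body mass is rarely reported directly; the pipeline converts mean
total body length (mm) to mass (g) with the power law mass = length^2.6.
Scaling exponents (e.g. venom yield against body mass, where metabolic
theory predicts 0.75) are estimated by ordinary least squares on
log10-log10 scale with a t-based 95% interval on the slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientDataError

#: Default exponent of the length (mm) -> mass (g) power law.
LENGTH_MASS_EXPONENT = 2.6


def length_to_mass(
    length_mm: float,
    exponent: float = LENGTH_MASS_EXPONENT,
    coefficient: float = 1.0,
) -> float:
    """Body mass (g) from total body length (mm): coefficient * length^exp.

    The published formula carries no explicit coefficient, so it defaults
    to 1.0 on the mm -> g scale; pass ``coefficient`` to rescale.
    """
    if not length_mm > 0:
        raise DomainError(f"length must be > 0, got {length_mm}")
    return coefficient * length_mm ** exponent


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10(y) = intercept + exponent * log10(x)."""

    exponent: float
    intercept: float
    ci_low: float
    ci_high: float
    stderr: float
    n: int

    def __post_init__(self):
        if not self.ci_low <= self.exponent <= self.ci_high:
            raise DomainError("interval must contain the point estimate")

    @property
    def coefficient(self) -> float:
        """Multiplicative coefficient on the raw scale, 10**intercept."""
        return 10.0 ** self.intercept

    def covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def fit_loglog_slope(x_values, y_values, conf: float = 0.95) -> PowerLawFit:
    """Estimate a scaling exponent by OLS on log10-log10 scale.

    Requires n >= 3 strictly positive pairs with variation in x.  The
    interval is exponent +/- t_{n-2} * SE; on noiseless power-law data the
    standard error is numerically zero and the interval collapses to the
    point estimate.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise InsufficientDataError(
            f"need at least 3 points, got {x.size}"
        )
    if np.any(x <= 0) or np.any(y <= 0):
        raise DomainError("all values must be > 0 for a log-log fit")
    lx, ly = np.log10(x), np.log10(y)
    if np.allclose(lx, lx[0]):
        raise InsufficientDataError("no variation in x; slope undefined")
    res = stats.linregress(lx, ly)
    tcrit = stats.t.ppf(0.5 + conf / 2.0, x.size - 2)
    half = tcrit * res.stderr
    return PowerLawFit(
        exponent=res.slope,
        intercept=res.intercept,
        ci_low=res.slope - half,
        ci_high=res.slope + half,
        stderr=res.stderr,
        n=int(x.size),
    )
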