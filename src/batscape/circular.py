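"""Circular statistics of migration bearings and great-circle bearings.

Bearings are degrees clockwise from true north in [0, 360).  The autumn ->
spring conversion is a point inversion (theta + 180 mod 360).  The angular
probability model is a von Mises density fitted by maximum likelihood and
standardized so its mode has density 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "circular_mean_deg",
    "mean_resultant_length",
    "invert_bearings",
    "VonMisesModel",
    "fit_vonmises",
    "initial_bearing",
]


def circular_mean_deg(bearings_deg) -> float:
    """Mean direction of a bearing sample, in [0, 360)."""
    b = np.asarray(bearings_deg, dtype=float)
    if b.size == 0:
        raise ValueError("empty bearing sample")
    rad = np.deg2rad(b)
    mean = np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())
    return float(np.rad2deg(mean) % 360.0)


def mean_resultant_length(bearings_deg) -> float:
    b = np.deg2rad(np.asarray(bearings_deg, dtype=float))
    if b.size == 0:
        raise ValueError("empty bearing sample")
    return float(np.hypot(np.sin(b).mean(), np.cos(b).mean()))


def invert_bearings(bearings_deg) -> np.ndarray:
    """Point-invert bearings: autumn headings become assumed spring headings.

    Out-of-range inputs are normalized into [0, 360) with a warning rather
    than rejected, since banding compilations often mix conventions.
    """
    b = np.asarray(bearings_deg, dtype=float)
    if np.any((b < 0) | (b >= 360)):
        warnings.warn("bearings outside [0, 360) normalized", stacklevel=2)
        b = b % 360.0
    return (b + 180.0) % 360.0


@dataclass
class VonMisesModel:
    """Standardized von Mises angular density: max value 1 at the mean.

    density(theta) = exp(kappa * (cos(theta - mu) - 1)); kappa = 0 gives the
    circular uniform (constant 1 after standardization).
    """

    mu_deg: float
    kappa: float
    n: int = 0
    sample_deg: np.ndarray | None = field(default=None, repr=False)

    def density(self, theta_deg) -> np.ndarray:
        th = np.deg2rad(np.asarray(theta_deg, dtype=float))
        mu = np.deg2rad(self.mu_deg)
        return np.exp(self.kappa * (np.cos(th - mu) - 1.0))


def _kappa_ml(rbar: float) -> float:
    # Best & Fisher approximation to the ML concentration given the mean
    # resultant length; standard in circular-statistics packages.
    if rbar >= 1.0:
        return np.inf
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)


def fit_vonmises(bearings_deg, min_n: int = 5) -> VonMisesModel:
    """Maximum-likelihood von Mises fit to a bearing sample (degrees)."""
    b = np.asarray(bearings_deg, dtype=float)
    if b.size < min_n:
        raise ValueError(f"need at least {min_n} bearings, got {b.size}")
    mu = circular_mean_deg(b)
    kappa = _kappa_ml(mean_resultant_length(b))
    if not np.isfinite(kappa):
        # all bearings identical: represent as a very tight mode
        kappa = 1e6
    return VonMisesModel(mu_deg=mu, kappa=float(kappa), n=int(b.size), sample_deg=b)


def initial_bearing(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Initial great-circle bearing from point 1 to point 2, spherical Earth.

    Degrees clockwise from true north in [0, 360).  Vectorized over the
    target coordinates.  The bearing is undefined for coincident points; the
    caller is expected to mask those.
    """
    p1, l1 = np.deg2rad(lat1), np.deg2rad(lon1)
    p2 = np.deg2rad(np.asarray(lat2, dtype=float))
    l2 = np.deg2rad(np.asarray(lon2, dtype=float))
    dl = l2 - l1
    y = np.sin(dl) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dl)
    return np.rad2deg(np.arctan2(y, x)) % 360.0
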