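"""Population receptive field parameters for a single cortical vertex."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from prftuning.angles import cartesian_to_polar, polar_to_cartesian


@dataclass(frozen=True)
class PRFParams:
    """pRF center, size, compressive exponent and model goodness of fit.

    ``polar_angle`` (deg, [-180, 180)) and ``eccentricity`` (deg, >= 0) locate
    the receptive field; ``sigma`` (deg, > 0) is its Gaussian size; ``exponent``
    in (0, 1] is the compressive spatial summation power (1 = linear);
    ``r2`` in [0, 1] is the variance the pRF model explained in the retinotopy
    data. ``x``/``y`` are the rectangular duals of (eccentricity, polar angle).
    """

    polar_angle: float
    eccentricity: float
    sigma: float
    exponent: float = 1.0
    r2: float = 1.0

    def __post_init__(self):
        if not -180.0 <= self.polar_angle < 180.0:
            raise ValueError(f"polar_angle {self.polar_angle} not in [-180, 180)")
        if self.eccentricity < 0:
            raise ValueError("eccentricity must be >= 0")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if not 0.0 < self.exponent <= 1.0:
            raise ValueError("exponent must lie in (0, 1]")
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError("r2 must lie in [0, 1]")

    @property
    def x(self) -> float:
        return float(polar_to_cartesian(self.polar_angle, self.eccentricity)[0])

    @property
    def y(self) -> float:
        return float(polar_to_cartesian(self.polar_angle, self.eccentricity)[1])

    @classmethod
    def from_cartesian(cls, x, y, sigma, exponent=1.0, r2=1.0) -> "PRFParams":
        theta, r = cartesian_to_polar(x, y)
        return cls(float(theta), float(r), sigma, exponent, r2)


def cartesian_roundtrip_error(prf: PRFParams) -> float:
    """Max abs error of the (theta, r) <-> (x, y) round trip, for testing."""
    theta, r = cartesian_to_polar(prf.x, prf.y)
    d_theta = abs(float(theta) - prf.polar_angle)
    d_theta = min(d_theta, 360.0 - d_theta)
    if prf.eccentricity == 0.0:
        d_theta = 0.0  # angle undefined at fixation
    return max(d_theta * np.pi / 180.0 * prf.eccentricity, abs(float(r) - prf.eccentricity))
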