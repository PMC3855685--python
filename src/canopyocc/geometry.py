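"""Planar footprint geometry.

Coordinates are planar metres in a local frame (east = +x, north = +y);
no projection metadata is carried. Azimuths are measured clockwise from
north, so the major-axis unit vector of an ellipse with azimuth ``az`` is
``(sin az, cos az)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["Ellipse"]


@dataclass(frozen=True)
class Ellipse:
    """Elliptical footprint: centre, semimajor axis, eccentricity, azimuth.

    A circle of diameter d is ``Ellipse(cx, cy, d / 2, 0.0, 0.0)``.
    """

    center_x: float
    center_y: float
    semimajor: float
    eccentricity: float = 0.0
    azimuth_deg: float = 0.0

    def __post_init__(self) -> None:
        if not self.semimajor > 0:
            raise ValueError(f"semimajor must be > 0, got {self.semimajor}")
        if not 0.0 <= self.eccentricity < 1.0:
            raise ValueError(
                f"eccentricity must be in [0, 1), got {self.eccentricity}"
            )

    @property
    def semiminor(self) -> float:
        return self.semimajor * math.sqrt(1.0 - self.eccentricity**2)

    @property
    def area(self) -> float:
        return math.pi * self.semimajor * self.semiminor

    def contains(self, x, y):
        """Vectorized point-in-ellipse test (boundary counts as inside)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        az = math.radians(self.azimuth_deg)
        dx = x - self.center_x
        dy = y - self.center_y
        u = dx * math.sin(az) + dy * math.cos(az)  # along major axis
        v = dx * math.cos(az) - dy * math.sin(az)  # along minor axis
        return (u / self.semimajor) ** 2 + (v / self.semiminor) ** 2 <= 1.0

    def sample_uniform(self, n: int, rng: np.random.Generator):
        """Draw n points uniformly inside the ellipse."""
        # uniform in unit disk, then affine map
        r = np.sqrt(rng.uniform(0.0, 1.0, n))
        theta = rng.uniform(0.0, 2.0 * math.pi, n)
        u = r * np.cos(theta) * self.semimajor
        v = r * np.sin(theta) * self.semiminor
        az = math.radians(self.azimuth_deg)
        x = self.center_x + u * math.sin(az) + v * math.cos(az)
        y = self.center_y + u * math.cos(az) - v * math.sin(az)
        return x, y
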