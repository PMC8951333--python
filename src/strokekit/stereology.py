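"""Stereological estimators: the 2D nucleator and the Cavalieri principle.

Infarct volumes in serial-section histology are estimated in two steps:
each section's infarct cross-sectional area is measured with the
isotropic 2D nucleator (rays from an interior point to the region
boundary, area ≈ π · mean(l²)), and areas are integrated over sections
with the Cavalieri estimator V = d · Σ aᵢ, where d is the distance
between sections.

The nucleator implemented here assumes the region is star-shaped about
the chosen central point (every ray meets the boundary exactly once);
under isotropic ray directions the estimator is unbiased for the area of
such regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NucleatorMeasurement",
    "SectionSeries",
    "systematic_rays",
    "random_rays",
    "nucleator_area",
    "cavalieri_volume",
]


@dataclass
class NucleatorMeasurement:
    """Ray-intercept lengths from a central point, with their directions.

    ``directions`` are angles in radians in [0, 2π); ``lengths`` are the
    distances (mm) from the central point to the region boundary along
    each direction. At least two rays are required.
    """

    directions: np.ndarray
    lengths: np.ndarray
    center: tuple[float, float] = (0.0, 0.0)
    star_shaped: bool = True

    def __post_init__(self) -> None:
        self.directions = np.atleast_1d(np.asarray(self.directions, dtype=float))
        self.lengths = np.atleast_1d(np.asarray(self.lengths, dtype=float))
        if self.directions.shape != self.lengths.shape:
            raise ValueError("directions and lengths must have equal length")
        if self.lengths.size < 2:
            raise ValueError("nucleator needs at least 2 rays")
        if np.any(self.lengths < 0):
            raise ValueError("intercept lengths must be nonnegative")
        if np.any((self.directions < 0) | (self.directions >= 2 * math.pi)):
            raise ValueError("directions must lie in [0, 2*pi)")
        if not self.star_shaped:
            raise ValueError(
                "multi-intercept nucleator for non-star-shaped regions is not "
                "supported; measurements must assert star_shaped=True"
            )


@dataclass
class SectionSeries:
    """Ordered cross-sectional areas aᵢ (mm²) at section spacing d (mm)."""

    areas: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        self.areas = np.atleast_1d(np.asarray(self.areas, dtype=float))
        if self.spacing <= 0:
            raise ValueError("section spacing must be positive")
        if self.areas.size == 0:
            raise ValueError("section series is empty")
        if np.any(self.areas < 0):
            raise ValueError("section areas must be nonnegative")


def systematic_rays(n: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """n equally spaced directions with a uniform random rotation.

    The systematic design has lower variance than independent uniform
    directions and is the default for nucleator sampling. Without an RNG
    the rotation is zero (deterministic fan).
    """
    if n < 2:
        raise ValueError("need at least 2 rays")
    phase = float(rng.uniform(0, 2 * math.pi / n)) if rng is not None else 0.0
    return (phase + 2 * math.pi * np.arange(n) / n) % (2 * math.pi)


def random_rays(n: int, rng: np.random.Generator) -> np.ndarray:
    """n independent isotropic directions."""
    if n < 2:
        raise ValueError("need at least 2 rays")
    return rng.uniform(0, 2 * math.pi, size=n)


def nucleator_area(m: NucleatorMeasurement) -> float:
    """Isotropic 2D nucleator area estimate: π · mean(lᵢ²)."""
    return float(math.pi * np.mean(m.lengths**2))


def cavalieri_volume(s: SectionSeries) -> float:
    """Cavalieri volume estimate from serial sections: V = d · Σ aᵢ."""
    return float(s.spacing * s.areas.sum())
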