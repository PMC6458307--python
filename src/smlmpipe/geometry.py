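"""Rectangular analysis regions.

Coordinates are continuous nanometres with the origin at the region corner
and y increasing upward.  Membership uses half-open intervals so that a
tiling of adjacent regions counts every point exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Region:
    """Axis-aligned rectangle [x0, x0+width) x [y0, y0+height), in nm."""

    x0: float
    y0: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("Region width and height must be positive")

    @property
    def area(self) -> float:
        """Area in nm^2."""
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (self.x0 + self.width / 2.0, self.y0 + self.height / 2.0)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Vectorized half-open membership test for an (n, 2) array."""
        xy = np.asarray(xy, dtype=float)
        x, y = xy[..., 0], xy[..., 1]
        return (
            (x >= self.x0)
            & (x < self.x0 + self.width)
            & (y >= self.y0)
            & (y < self.y0 + self.height)
        )

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n i.i.d. uniform points, shape (n, 2)."""
        if n < 0:
            raise ValueError("n must be non-negative")
        lo = np.array([self.x0, self.y0])
        span = np.array([self.width, self.height])
        return lo + rng.random((n, 2)) * span

    def wrap(self, xy: np.ndarray) -> np.ndarray:
        """Map points onto the region treating it as a torus."""
        xy = np.asarray(xy, dtype=float).copy()
        xy[..., 0] = self.x0 + np.mod(xy[..., 0] - self.x0, self.width)
        xy[..., 1] = self.y0 + np.mod(xy[..., 1] - self.y0, self.height)
        return xy
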