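"""Observation windows for planar point patterns.

Two window shapes cover everything the analyses need: circular aquaria
(disks, coordinates in cm with the origin at the tank centre) and
rectangular sea-pen survey extents (metres).  Windows know their area,
membership predicate, how to draw uniform points from themselves, and how
to dilate themselves (used when simulating cluster processes without edge
bias).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class Window:
    """Common interface for observation windows."""

    @property
    def area(self) -> float:
        raise NotImplementedError

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean membership (boundary inclusive) for an (n, 2) array."""
        raise NotImplementedError

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def dilate(self, margin: float) -> "Window":
        raise NotImplementedError


@dataclass(frozen=True)
class Disk(Window):
    """Circular window, e.g. a 60 cm aquarium is ``Disk((0, 0), 30.0)``."""

    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 30.0

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError(f"disk radius must be positive, got {self.radius}")

    @property
    def area(self) -> float:
        return float(np.pi * self.radius**2)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        d2 = (xy[:, 0] - self.center[0]) ** 2 + (xy[:, 1] - self.center[1]) ** 2
        # small epsilon so points placed exactly on the rim stay inside
        return d2 <= self.radius**2 * (1.0 + 1e-12)

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        # exact polar sampling: radius ~ R*sqrt(U) gives uniform area density
        u = rng.random(n)
        theta = rng.random(n) * 2.0 * np.pi
        r = self.radius * np.sqrt(u)
        return np.column_stack(
            (self.center[0] + r * np.cos(theta), self.center[1] + r * np.sin(theta))
        )

    def dilate(self, margin: float) -> "Disk":
        return Disk(self.center, self.radius + margin)


@dataclass(frozen=True)
class Rectangle(Window):
    """Axis-aligned rectangular window [xmin, xmax] x [ymin, ymax]."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(
                "rectangle must have positive side lengths, got "
                f"[{self.xmin}, {self.xmax}] x [{self.ymin}, {self.ymax}]"
            )

    @property
    def area(self) -> float:
        return float((self.xmax - self.xmin) * (self.ymax - self.ymin))

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return (
            (xy[:, 0] >= self.xmin)
            & (xy[:, 0] <= self.xmax)
            & (xy[:, 1] >= self.ymin)
            & (xy[:, 1] <= self.ymax)
        )

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        x = rng.uniform(self.xmin, self.xmax, n)
        y = rng.uniform(self.ymin, self.ymax, n)
        return np.column_stack((x, y))

    def dilate(self, margin: float) -> "Rectangle":
        return Rectangle(
            self.xmin - margin, self.xmax + margin, self.ymin - margin, self.ymax + margin
        )
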