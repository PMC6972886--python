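"""Regular 2-D grids over collective-variable space."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError


@dataclass(frozen=True)
class GridSpec:
    """Axis specification for a regular 2-D CV grid.

    Axis 1 is conventionally the methyl–methyl distance (Å), axis 2 the
    Au–C coordination number, but the grid itself is unit-agnostic.
    """

    x_min: float
    x_max: float
    n_x: int
    y_min: float
    y_max: float
    n_y: int

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ParameterError("grid bounds must satisfy min < max")
        if self.n_x < 2 or self.n_y < 2:
            raise ParameterError("grid needs at least 2 points per axis")

    @property
    def x(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.n_x)

    @property
    def y(self) -> np.ndarray:
        return np.linspace(self.y_min, self.y_max, self.n_y)

    @property
    def spacing(self) -> tuple[float, float]:
        return (
            (self.x_max - self.x_min) / (self.n_x - 1),
            (self.y_max - self.y_min) / (self.n_y - 1),
        )


@dataclass
class FESGrid:
    """Free energy (or bias) values on a regular 2-D CV grid, kcal/mol.

    ``values[i, j]`` corresponds to ``(x[i], y[j])``.
    """

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    normalized: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.x.size, self.y.size):
            raise ParameterError(
                f"values shape {self.values.shape} does not match axes "
                f"({self.x.size}, {self.y.size})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("FES values must be finite everywhere")

    @property
    def spacing(self) -> tuple[float, float]:
        return float(self.x[1] - self.x[0]), float(self.y[1] - self.y[0])

    def normalize(self) -> "FESGrid":
        """Shift so the minimum is zero (in place); returns self."""
        self.values = self.values - self.values.min()
        self.normalized = True
        return self

    def contains(self, point) -> bool:
        px, py = float(point[0]), float(point[1])
        return (self.x[0] <= px <= self.x[-1]) and (self.y[0] <= py <= self.y[-1])

    def argmin_point(self, x_range=None, y_range=None) -> np.ndarray:
        """Grid point of minimum value, optionally restricted to axis ranges."""
        mask = np.ones_like(self.values, dtype=bool)
        if x_range is not None:
            mask &= ((self.x >= x_range[0]) & (self.x <= x_range[1]))[:, None]
        if y_range is not None:
            mask &= ((self.y >= y_range[0]) & (self.y <= y_range[1]))[None, :]
        if not mask.any():
            raise ParameterError("restriction excludes every grid point")
        masked = np.where(mask, self.values, np.inf)
        i, j = np.unravel_index(np.argmin(masked), masked.shape)
        return np.array([self.x[i], self.y[j]])
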