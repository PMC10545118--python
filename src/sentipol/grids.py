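"""Uniform finite-volume grids on [0,1] and [0,1]^2 and cell-averaged densities.

Every density in the package — empirical histograms, analytic Beta marginals,
finite-volume solver states — lives on these grids as *cell averages*, so that
binned data and PDE solutions are directly comparable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid1D", "Grid2D", "Marginal1D", "DensityField2D"]


@dataclass(frozen=True)
class Grid1D:
    """``n`` equal cells tiling [0, 1].

    Cell ``i`` covers ``[i*dw, (i+1)*dw)``; the last cell is right-closed so a
    score of exactly 1.0 is kept.
    """

    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"grid needs at least 2 cells, got n={self.n}")

    @property
    def dw(self) -> float:
        return 1.0 / self.n

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n + 1)

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n) + 0.5) * self.dw

    @property
    def interior_faces(self) -> np.ndarray:
        """Coordinates of the n-1 faces between adjacent cells."""
        return np.arange(1, self.n) * self.dw

    def locate(self, w: np.ndarray) -> np.ndarray:
        """Cell index for each coordinate; w == 1.0 maps to the last cell."""
        w = np.asarray(w, dtype=float)
        if np.any((w < 0.0) | (w > 1.0)):
            raise ValueError("coordinates must lie in [0, 1]")
        return np.minimum((w * self.n).astype(np.int64), self.n - 1)


@dataclass(frozen=True)
class Grid2D:
    """Tensor grid of ``n_plus`` x ``n_minus`` cells on the opinion square.

    Axis 0 indexes the positive score w+, axis 1 the negative score w-.
    """

    n_plus: int = 20
    n_minus: int = 20

    def __post_init__(self) -> None:
        if self.n_plus < 2 or self.n_minus < 2:
            raise ValueError("need at least 2 cells per axis")

    @property
    def axis_plus(self) -> Grid1D:
        return Grid1D(self.n_plus)

    @property
    def axis_minus(self) -> Grid1D:
        return Grid1D(self.n_minus)

    @property
    def dw_plus(self) -> float:
        return 1.0 / self.n_plus

    @property
    def dw_minus(self) -> float:
        return 1.0 / self.n_minus

    @property
    def cell_area(self) -> float:
        return self.dw_plus * self.dw_minus


@dataclass
class Marginal1D:
    """Cell-averaged nonnegative density on a 1-D grid."""

    grid: Grid1D
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n,):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid n={self.grid.n}"
            )
        if np.any(self.values < -1e-15):
            raise ValueError("density values must be nonnegative")

    @property
    def mass(self) -> float:
        return float(self.values.sum() * self.grid.dw)

    @property
    def mean(self) -> float:
        if self.mass <= 0.0:
            raise ValueError("mean undefined for a zero-mass density")
        return float((self.grid.centers * self.values).sum() * self.grid.dw / self.mass)

    @property
    def variance(self) -> float:
        m = self.mean
        return float(
            ((self.grid.centers - m) ** 2 * self.values).sum() * self.grid.dw / self.mass
        )

    def normalized(self) -> "Marginal1D":
        if self.mass <= 0.0:
            raise ValueError("cannot normalize a zero-mass density")
        return Marginal1D(self.grid, self.values / self.mass)


@dataclass
class DensityField2D:
    """Cell-averaged nonnegative density on a :class:`Grid2D`.

    ``values[i, j]`` is the average density over the cell with positive-score
    index ``i`` and negative-score index ``j``.
    """

    grid: Grid2D
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.grid.n_plus, self.grid.n_minus)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != grid shape {expected}")
        if np.any(self.values < -1e-12):
            raise ValueError("density values must be nonnegative")

    @property
    def mass(self) -> float:
        return float(self.values.sum() * self.grid.cell_area)

    def marginal_plus(self) -> Marginal1D:
        """Integrate out w-: g(w+) = ∫ f dw-."""
        return Marginal1D(self.grid.axis_plus, self.values.sum(axis=1) * self.grid.dw_minus)

    def marginal_minus(self) -> Marginal1D:
        """Integrate out w+: h(w-) = ∫ f dw+."""
        return Marginal1D(self.grid.axis_minus, self.values.sum(axis=0) * self.grid.dw_plus)

    def copy(self) -> "DensityField2D":
        return DensityField2D(self.grid, self.values.copy())
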