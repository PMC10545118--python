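"""Analytic stationary marginals of the opinion dynamics.

With product diffusivity the mean-field dynamics relaxes, marginal by
marginal, to a Beta distribution

    g_inf(w) = C w^(a-1) (1-w)^(b-1),   a = m/mu,  b = (1-m)/mu,

parameterized by its mean location ``m`` in (0,1) and a shape ratio ``mu > 0``
(small mu: concentrated around m; large mu: mass pushed onto the boundaries).
When the population splits into susceptible- and recovered-origin
subpopulations, the observable marginal is a two-component Beta *mixture*,
which can be unimodal or bimodal — the model's signature of polarization.

Densities are represented as cell averages (CDF differences over cells), so
boundary-unbounded cases (a < 1 or b < 1) keep exact cell mass.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grids import Grid1D, Marginal1D

__all__ = [
    "BetaSpec",
    "BetaMixtureSpec",
    "beta_shape",
    "stationary_marginal",
    "stationary_mixture",
    "count_modes",
]


def beta_shape(m: float, mu: float) -> tuple[float, float]:
    """Beta shape parameters (a, b) = (m/mu, (1-m)/mu) of the stationary marginal."""
    if not 0.0 < m < 1.0:
        raise ValueError(f"mean location m must lie in (0, 1), got {m}")
    if mu <= 0.0:
        raise ValueError(f"shape ratio mu must be positive, got {mu}")
    return m / mu, (1.0 - m) / mu


@dataclass(frozen=True)
class BetaSpec:
    """Stationary Beta marginal, located by mean ``m`` and shape ratio ``mu``."""

    m: float
    mu: float

    def __post_init__(self) -> None:
        beta_shape(self.m, self.mu)  # validates

    @property
    def a(self) -> float:
        return self.m / self.mu

    @property
    def b(self) -> float:
        return (1.0 - self.m) / self.mu

    @classmethod
    def from_shape(cls, a: float, b: float) -> "BetaSpec":
        if a <= 0.0 or b <= 0.0:
            raise ValueError("shape parameters must be positive")
        return cls(m=a / (a + b), mu=1.0 / (a + b))

    @classmethod
    def from_rates(cls, m: float, lam: float, sigma: float) -> "BetaSpec":
        """Spec from a (mean, compromise rate, noise strength) triple using the
        reporting convention ``mu = lambda / sigma^2``.

        This is the convention in which calibrated rate pairs are printed in
        equilibrium-fitting tables; only the ratio is identified by the
        stationary state.
        """
        if lam <= 0.0 or sigma <= 0.0:
            raise ValueError("lambda and sigma must be positive")
        return cls(m=m, mu=lam / (sigma * sigma))

    def pdf(self, w: np.ndarray) -> np.ndarray:
        return stats.beta.pdf(w, self.a, self.b)

    def cdf(self, w: np.ndarray) -> np.ndarray:
        return stats.beta.cdf(w, self.a, self.b)

    def cell_averages(self, grid: Grid1D) -> np.ndarray:
        """Exact per-cell mass divided by cell width (telescoping CDF differences)."""
        return np.diff(self.cdf(grid.edges)) / grid.dw

    def variance(self) -> float:
        a, b = self.a, self.b
        return a * b / ((a + b) ** 2 * (a + b + 1.0))


@dataclass(frozen=True)
class BetaMixtureSpec:
    """Convex combination of a susceptible- and a recovered-origin component."""

    weight_S: float
    spec_S: BetaSpec
    spec_R: BetaSpec

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight_S <= 1.0:
            raise ValueError(f"mixture weight must lie in [0, 1], got {self.weight_S}")

    def pdf(self, w: np.ndarray) -> np.ndarray:
        return self.weight_S * self.spec_S.pdf(w) + (1.0 - self.weight_S) * self.spec_R.pdf(w)

    def cdf(self, w: np.ndarray) -> np.ndarray:
        return self.weight_S * self.spec_S.cdf(w) + (1.0 - self.weight_S) * self.spec_R.cdf(w)

    def cell_averages(self, grid: Grid1D) -> np.ndarray:
        return self.weight_S * self.spec_S.cell_averages(grid) + (
            1.0 - self.weight_S
        ) * self.spec_R.cell_averages(grid)

    @property
    def mean(self) -> float:
        return self.weight_S * self.spec_S.m + (1.0 - self.weight_S) * self.spec_R.m

    def interior_mode(self) -> float | None:
        """Abscissa of the interior mode of the interior-peaked component.

        For a Beta component with a > 1 and b > 1 the mode sits at
        (a-1)/(a+b-2).  Returns the mode of the component that has one,
        preferring the heavier-peaked (larger-mean) component; None if
        neither component is interior-peaked.
        """
        for spec in sorted((self.spec_S, self.spec_R), key=lambda s: s.m, reverse=True):
            if spec.a > 1.0 and spec.b > 1.0:
                return (spec.a - 1.0) / (spec.a + spec.b - 2.0)
        return None


def stationary_marginal(spec: BetaSpec, grid: Grid1D) -> Marginal1D:
    """Cell-averaged stationary Beta marginal on ``grid`` (unit mass exactly)."""
    return Marginal1D(grid, spec.cell_averages(grid))


def stationary_mixture(mix: BetaMixtureSpec, grid: Grid1D) -> Marginal1D:
    """Cell-averaged stationary Beta-mixture marginal on ``grid``."""
    return Marginal1D(grid, mix.cell_averages(grid))


def count_modes(marginal: Marginal1D) -> tuple[int, list[float]]:
    """Number and locations of local maxima of the cell values.

    Conventions: runs of equal values collapse to a single plateau located at
    their center; a plateau is a mode when every existing neighbor is strictly
    lower (so a boundary cell strictly above its single neighbor counts, and a
    globally constant density has exactly one mode).
    """
    v = marginal.values
    if v.size < 3:
        raise ValueError("mode counting needs at least 3 cells")
    centers = marginal.grid.centers
    # compress into plateaus of constant value
    starts = [0]
    for i in range(1, v.size):
        if v[i] != v[starts[-1]]:
            starts.append(i)
    starts.append(v.size)
    modes: list[float] = []
    for k in range(len(starts) - 1):
        lo, hi = starts[k], starts[k + 1]
        left_lower = k == 0 or v[starts[k - 1]] < v[lo]
        right_lower = k == len(starts) - 2 or v[starts[k + 1]] < v[lo]
        if left_lower and right_lower:
            modes.append(float(centers[lo:hi].mean()))
    return len(modes), modes
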