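"""Nonlinear least-squares calibration of Beta-mixture equilibria.

Given an empirical marginal (a binned, unit-mass sentiment histogram), find
the two-component stationary Beta mixture closest to it in the discrete,
cell-width-weighted L2 norm:

    min   sum_i dw * ( w hS(c_i; m_S, mu_S) + (1-w) hR(c_i; m_R, mu_R) - hbar_i )^2

over the mixture weight and the component parameters.  Two parameterizations
are offered: ``shape`` — (weight, m_S, mu_S, m_R, mu_R), the identifiable
one, used by default — and ``rates`` — (weight, m_S, lambda_S, sigma_S, m_R,
lambda_R, sigma_R), mirroring how calibrated parameters are conventionally
reported; the stationary state depends on (lambda, sigma) only through
mu = lambda/sigma^2, so in that mode the individual rates are whatever the
optimizer found and mu is reported alongside.

The objective is non-convex (label switching, boundary-spiked components), so
the solver runs bounded trust-region least squares from a seeded
Latin-hypercube of starting points and keeps the best converged fit, with
components ordered by ascending mean.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .equilibria import BetaMixtureSpec, BetaSpec
from .grids import Marginal1D

__all__ = ["FitOptions", "FitResult", "mixture_residual", "fit_beta_mixture"]

_PARAMETERIZATIONS = ("shape", "rates")


@dataclass(frozen=True)
class FitOptions:
    parameterization: str = "shape"
    n_starts: int = 32
    seed: int = 0
    tolerance: float = 1e-12
    m_bounds: tuple[float, float] = (1e-3, 1.0 - 1e-3)
    mu_bounds: tuple[float, float] = (1e-3, 20.0)
    rate_bounds: tuple[float, float] = (1e-4, 5.0)

    def __post_init__(self) -> None:
        if self.parameterization not in _PARAMETERIZATIONS:
            raise ValueError(f"parameterization must be one of {_PARAMETERIZATIONS}")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")

    @property
    def n_params(self) -> int:
        return 5 if self.parameterization == "shape" else 7

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        if self.parameterization == "shape":
            lo = [0.0, self.m_bounds[0], self.mu_bounds[0], self.m_bounds[0], self.mu_bounds[0]]
            hi = [1.0, self.m_bounds[1], self.mu_bounds[1], self.m_bounds[1], self.mu_bounds[1]]
        else:
            rb = self.rate_bounds
            lo = [0.0, self.m_bounds[0], rb[0], rb[0], self.m_bounds[0], rb[0], rb[0]]
            hi = [1.0, self.m_bounds[1], rb[1], rb[1], self.m_bounds[1], rb[1], rb[1]]
        return np.array(lo), np.array(hi)


def theta_to_mixture(theta: np.ndarray, parameterization: str = "shape") -> BetaMixtureSpec:
    """Decode a parameter vector into a mixture spec."""
    theta = np.asarray(theta, dtype=float)
    if parameterization == "shape":
        w, m_s, mu_s, m_r, mu_r = theta
        return BetaMixtureSpec(w, BetaSpec(m_s, mu_s), BetaSpec(m_r, mu_r))
    w, m_s, lam_s, sig_s, m_r, lam_r, sig_r = theta
    return BetaMixtureSpec(
        w, BetaSpec.from_rates(m_s, lam_s, sig_s), BetaSpec.from_rates(m_r, lam_r, sig_r)
    )


def _residual_vector(
    theta: np.ndarray, empirical: Marginal1D, parameterization: str
) -> np.ndarray:
    mix = theta_to_mixture(theta, parameterization)
    dw = empirical.grid.dw
    return np.sqrt(dw) * (mix.cell_averages(empirical.grid) - empirical.values)


def mixture_residual(
    theta: np.ndarray, empirical: Marginal1D, parameterization: str = "shape",
    options: FitOptions | None = None,
) -> float:
    """Discrete squared-L2 misfit of the mixture at ``theta`` to the histogram."""
    options = options or FitOptions(parameterization=parameterization)
    lo, hi = options.bounds()
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < lo) or np.any(theta > hi):
        raise ValueError("theta outside fitting bounds")
    r = _residual_vector(theta, empirical, parameterization)
    return float(r @ r)


@dataclass
class FitResult:
    mixture: BetaMixtureSpec
    theta: np.ndarray
    residual_norm: float  # squared L2 misfit at the optimum
    converged: bool
    degenerate_component: bool  # weight pinned near 0 or 1
    parameterization: str
    start_residuals: np.ndarray  # best residual reached from each start

    @property
    def weight_S(self) -> float:
        return self.mixture.weight_S

    def mu_values(self) -> tuple[float, float]:
        """(mu_S, mu_R): the identified shape ratios, whatever the parameterization."""
        return self.mixture.spec_S.mu, self.mixture.spec_R.mu


def _order_components(theta: np.ndarray, parameterization: str) -> np.ndarray:
    """Resolve label switching: component with the smaller mean is reported first."""
    theta = theta.copy()
    if parameterization == "shape":
        if theta[1] > theta[3]:
            theta = np.array([1.0 - theta[0], theta[3], theta[4], theta[1], theta[2]])
    else:
        if theta[1] > theta[4]:
            theta = np.array(
                [1.0 - theta[0], theta[4], theta[5], theta[6], theta[1], theta[2], theta[3]]
            )
    return theta


def fit_beta_mixture(empirical: Marginal1D, options: FitOptions | None = None) -> FitResult:
    """Best-of-multi-start bounded least squares fit of a two-Beta mixture.

    Starting points are a seeded Latin hypercube inside the bounds; the best
    converged solution (lowest squared misfit) is returned with components
    ordered by ascending mean.
    """
    options = options or FitOptions()
    if empirical.grid.n < 8:
        raise ValueError("need at least 8 cells to fit a five-parameter mixture")
    if abs(empirical.mass - 1.0) > 1e-8:
        raise ValueError("empirical marginal must be normalized to unit mass")
    lo, hi = options.bounds()
    sampler = qmc.LatinHypercube(d=options.n_params, seed=options.seed)
    starts = qmc.scale(sampler.random(options.n_starts), lo, hi)

    best = None
    start_costs = np.full(options.n_starts, np.inf)
    for k, x0 in enumerate(starts):
        try:
            sol = least_squares(
                _residual_vector,
                x0,
                bounds=(lo, hi),
                args=(empirical, options.parameterization),
                xtol=options.tolerance,
                ftol=options.tolerance,
                gtol=options.tolerance,
                method="trf",
            )
        except Exception:
            continue
        if not sol.success:
            continue
        cost = float(2.0 * sol.cost)  # least_squares cost = 0.5 * sum r^2
        start_costs[k] = cost
        if best is None or cost < best[0]:
            best = (cost, sol.x)
    if best is None:
        raise RuntimeError("no fitting start converged; inspect the input histogram")

    cost, theta = best
    theta = _order_components(theta, options.parameterization)
    mixture = theta_to_mixture(theta, options.parameterization)
    degenerate = theta[0] < 1e-3 or theta[0] > 1.0 - 1e-3
    return FitResult(
        mixture=mixture,
        theta=theta,
        residual_norm=cost,
        converged=True,
        degenerate_component=degenerate,
        parameterization=options.parameterization,
        start_residuals=start_costs,
    )
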