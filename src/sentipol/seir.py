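"""Opinion-independent fake-news compartment dynamics.

Population fractions move through Susceptible -> Exposed -> Infectious
(spreaders) -> Recovered (stiflers) compartments:

    dS/dt = -beta S I + (1-alpha) gamma I
    dE/dt =  beta S I - zeta E
    dI/dt = (1-eta) zeta E - gamma I
    dR/dt =  eta zeta E + alpha gamma I

where beta is the contact rate with spreaders, 1/zeta the mean latency,
1/gamma the mean spreading time, eta the probability of skipping the
spreading phase and alpha the probability of permanent removal afterwards.
The default regime eta = 0, alpha = 1 (exposed agents always spread, spreaders
are always removed) admits the classical final-size relation

    ln( S_inf / S(0) ) = -(beta/gamma) (R_inf - R(0)),   R_inf = 1 - S_inf,

which links the contact rate to the fraction of the population never reached
by the fake news, and is used in reverse to calibrate beta from a fitted
equilibrium susceptible fraction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "EpidemicParams",
    "CompartmentMasses",
    "MassTrajectory",
    "seir_derivatives",
    "integrate_seir",
    "final_size",
    "invert_final_size",
]

COMPARTMENTS = ("S", "E", "I", "R")


@dataclass(frozen=True)
class EpidemicParams:
    """Rates of the fake-news compartment dynamics (all times in days)."""

    beta: float
    zeta: float = 1.0
    gamma: float = 1.0
    alpha: float = 1.0
    eta: float = 0.0

    def __post_init__(self) -> None:
        for name in ("beta", "zeta", "gamma"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("alpha", "eta"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class CompartmentMasses:
    rho_S: float
    rho_E: float
    rho_I: float
    rho_R: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < -1e-12):
            raise ValueError("compartment masses must be nonnegative")
        if abs(arr.sum() - 1.0) > 1e-10:
            raise ValueError(f"compartment masses must sum to 1, got {arr.sum():.12f}")

    def as_array(self) -> np.ndarray:
        return np.array([self.rho_S, self.rho_E, self.rho_I, self.rho_R], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "CompartmentMasses":
        return cls(*(float(x) for x in arr))


@dataclass
class MassTrajectory:
    """Time series of the four compartment fractions; ``masses[k]`` at ``times[k]``."""

    times: np.ndarray
    masses: np.ndarray  # shape (T, 4), columns ordered S, E, I, R

    @property
    def terminal(self) -> CompartmentMasses:
        return CompartmentMasses.from_array(self.masses[-1])


def seir_derivatives(state: np.ndarray | CompartmentMasses, params: EpidemicParams) -> np.ndarray:
    """Right-hand side of the compartment ODE at ``state`` (sums to zero exactly)."""
    if isinstance(state, CompartmentMasses):
        state = state.as_array()
    s, e, i, _ = state
    incidence = params.beta * s * i
    latency = params.zeta * e
    recovery = params.gamma * i
    return np.array(
        [
            -incidence + (1.0 - params.alpha) * recovery,
            incidence - latency,
            (1.0 - params.eta) * latency - recovery,
            params.eta * latency + params.alpha * recovery,
        ]
    )


def integrate_seir(
    params: EpidemicParams,
    init: CompartmentMasses,
    t_final: float,
    dt: float = 1e-3,
    store_every: int | None = None,
) -> MassTrajectory:
    """Classical RK4 integration with fixed step ``dt``.

    ``store_every`` keeps one sample every that many steps (defaults to about
    1000 stored points); the final state is always stored.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    if t_final < 0.0:
        raise ValueError("t_final must be nonnegative")
    n_steps = int(round(t_final / dt))
    if store_every is None:
        store_every = max(1, n_steps // 1000)
    y = init.as_array()
    times = [0.0]
    states = [y.copy()]
    for k in range(n_steps):
        k1 = seir_derivatives(y, params)
        k2 = seir_derivatives(y + 0.5 * dt * k1, params)
        k3 = seir_derivatives(y + 0.5 * dt * k2, params)
        k4 = seir_derivatives(y + dt * k3, params)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if np.any(y < -1e-9):
            raise RuntimeError(
                f"negative compartment mass at t={(k + 1) * dt:.4f}; decrease dt"
            )
        if (k + 1) % store_every == 0 or k == n_steps - 1:
            times.append((k + 1) * dt)
            states.append(y.copy())
    return MassTrajectory(np.array(times), np.array(states))


def _final_size_residual(x: float, beta: float, gamma: float, rho_s0: float, rho_r0: float,
                         verbatim: bool) -> float:
    if verbatim:
        # relation as sometimes printed, without sign / initial-removed correction
        return math.log(x / rho_s0) - (beta / gamma) * (1.0 - x)
    return math.log(x / rho_s0) + (beta / gamma) * ((1.0 - x) - rho_r0)


def final_size(
    beta: float,
    gamma: float,
    init: CompartmentMasses,
    verbatim: bool = False,
    tol: float = 1e-12,
) -> float:
    """Equilibrium susceptible fraction ``rho_S_inf`` in the eta=0, alpha=1 regime.

    Solves ``ln(x/S0) = -(beta/gamma)((1-x) - R0)`` for x in (0, S0) by
    bracketed root finding.  ``verbatim=True`` switches to the uncorrected
    variant ``ln(x/S0) = (beta/gamma)(1-x)`` for comparison.
    """
    if beta < 0.0 or gamma <= 0.0:
        raise ValueError("need beta >= 0 and gamma > 0")
    rho_s0 = init.rho_S
    if rho_s0 <= 0.0:
        raise ValueError("initial susceptible fraction must be positive")
    if beta == 0.0:
        return rho_s0
    lo, hi = 1e-14, rho_s0 * (1.0 - 1e-14)
    f_lo = _final_size_residual(lo, beta, gamma, rho_s0, init.rho_R, verbatim)
    f_hi = _final_size_residual(hi, beta, gamma, rho_s0, init.rho_R, verbatim)
    if f_lo * f_hi > 0.0:
        raise ValueError("final-size relation has no sign change in (0, rho_S(0))")
    return float(
        brentq(
            _final_size_residual,
            lo,
            hi,
            args=(beta, gamma, rho_s0, init.rho_R, verbatim),
            xtol=tol,
            rtol=8.9e-16,
        )
    )


def invert_final_size(rho_s_inf: float, gamma: float, init: CompartmentMasses) -> float:
    """Contact rate beta reproducing a given equilibrium susceptible fraction.

    Closed form from the final-size relation:
    ``beta = gamma * ln(S0 / S_inf) / (1 - S_inf - R0)``.
    """
    rho_s0, rho_r0 = init.rho_S, init.rho_R
    if not 0.0 < rho_s_inf < rho_s0:
        raise ValueError(
            f"rho_S_inf must lie strictly between 0 and rho_S(0)={rho_s0}, got {rho_s_inf}"
        )
    denom = 1.0 - rho_s_inf - rho_r0
    if denom <= 0.0:
        raise ValueError("equilibrium removed fraction must exceed its initial value")
    return gamma * math.log(rho_s0 / rho_s_inf) / denom
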