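"""Coupled opinion-formation / fake-news-dissemination kinetic system.

One opinion density per compartment, f_S, f_E, f_I, f_R on [0,1]^2, evolving
under (i) the mean-field opinion operator of :mod:`sentipol.meanfield_fp`
with per-compartment rates but drift toward the *global* means

    m± = sum_J rho_J m_J±,

and (ii) compartment exchange driven by the local incidence functional

    K(f_S, f_I)(w) = f_S(w) * ∫ kappa(w*) f_I(w*) dw*,

with a contact function kappa that is constant (kappa = beta) or separable
(kappa(w) = beta k(w+) kbar(w-)).  A time step applies, in order, the w+
sweeps, the w- sweeps (both semi-implicit) and an explicit Euler exchange
step; total mass is conserved exactly by all three.

The module also provides the closed moment ODE system (masses and
per-compartment means) that the kinetic solution must reproduce when the
contact function is constant — the strongest whole-system cross-check.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .grids import DensityField2D, Grid2D, Marginal1D
from .meanfield_fp import fp_sweep_1d, scheme_coefficients
from .params import OpinionParams
from .seir import COMPARTMENTS, CompartmentMasses, EpidemicParams

__all__ = [
    "CompartmentFields",
    "ContactFunction",
    "MomentTrajectory",
    "incidence_operator",
    "epidemic_exchange_step",
    "solve_coupled",
    "moment_ode_oracle",
]


@dataclass(frozen=True)
class ContactFunction:
    """Opinion-dependent contact rate kappa(w) >= 0.

    ``constant``: kappa = beta everywhere.  ``separable``: kappa(w) =
    beta * k_plus(w+) * k_minus(w-) with nonnegative factor callables.
    """

    beta: float
    kind: str = "constant"
    k_plus: Callable[[np.ndarray], np.ndarray] | None = None
    k_minus: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.beta < 0.0:
            raise ValueError("contact scale beta must be nonnegative")
        if self.kind not in ("constant", "separable"):
            raise ValueError(f"unknown contact kind {self.kind!r}")
        if self.kind == "separable" and (self.k_plus is None or self.k_minus is None):
            raise ValueError("separable contact needs both factor functions")

    def on_grid(self, grid: Grid2D) -> np.ndarray:
        """kappa evaluated at cell centers, shape (n_plus, n_minus)."""
        if self.kind == "constant":
            return np.full((grid.n_plus, grid.n_minus), self.beta)
        kp = np.asarray(self.k_plus(grid.axis_plus.centers), dtype=float)
        km = np.asarray(self.k_minus(grid.axis_minus.centers), dtype=float)
        if np.any(kp < 0.0) or np.any(km < 0.0):
            raise ValueError("contact factors must be nonnegative")
        return self.beta * np.outer(kp, km)


@dataclass
class CompartmentFields:
    """One opinion density per compartment on a shared grid."""

    f_S: DensityField2D
    f_E: DensityField2D
    f_I: DensityField2D
    f_R: DensityField2D

    def __post_init__(self) -> None:
        grids = {id(f.grid) for f in self.as_dict().values()}
        g0 = self.f_S.grid
        for f in self.as_dict().values():
            if (f.grid.n_plus, f.grid.n_minus) != (g0.n_plus, g0.n_minus):
                raise ValueError("all compartments must share one grid")

    def as_dict(self) -> dict[str, DensityField2D]:
        return {"S": self.f_S, "E": self.f_E, "I": self.f_I, "R": self.f_R}

    @property
    def grid(self) -> Grid2D:
        return self.f_S.grid

    @property
    def total_mass(self) -> float:
        return sum(f.mass for f in self.as_dict().values())

    def masses(self) -> CompartmentMasses:
        d = self.as_dict()
        return CompartmentMasses.from_array(np.array([d[c].mass for c in COMPARTMENTS]))

    def global_means(self) -> tuple[float, float]:
        """Mass-weighted global means (m+, m-) over all compartments."""
        grid = self.grid
        total = np.zeros((grid.n_plus, grid.n_minus))
        for f in self.as_dict().values():
            total += f.values
        g = Marginal1D(grid.axis_plus, total.sum(axis=1) * grid.dw_minus).normalized()
        h = Marginal1D(grid.axis_minus, total.sum(axis=0) * grid.dw_plus).normalized()
        return g.mean, h.mean

    def total_marginal_minus(self) -> Marginal1D:
        grid = self.grid
        total = sum(f.values for f in self.as_dict().values())
        return Marginal1D(grid.axis_minus, total.sum(axis=0) * grid.dw_plus)

    def total_marginal_plus(self) -> Marginal1D:
        grid = self.grid
        total = sum(f.values for f in self.as_dict().values())
        return Marginal1D(grid.axis_plus, total.sum(axis=1) * grid.dw_minus)

    @classmethod
    def from_shared_shape(
        cls, shape: DensityField2D, masses: CompartmentMasses
    ) -> "CompartmentFields":
        """All compartments share one unit-mass shape, scaled by initial masses."""
        if abs(shape.mass - 1.0) > 1e-8:
            raise ValueError("shared shape must have unit mass")
        vals = [shape.values * rho for rho in masses.as_array()]
        return cls(*(DensityField2D(shape.grid, v) for v in vals))

    def copy(self) -> "CompartmentFields":
        return CompartmentFields(*(f.copy() for f in (self.f_S, self.f_E, self.f_I, self.f_R)))


def incidence_operator(
    f_S: DensityField2D, f_I: DensityField2D, contact: ContactFunction
) -> DensityField2D:
    """Local incidence K(w) = f_S(w) * ∫ kappa f_I dw* by cell-center quadrature."""
    if (f_S.grid.n_plus, f_S.grid.n_minus) != (f_I.grid.n_plus, f_I.grid.n_minus):
        raise ValueError("susceptible and infectious fields must share the grid")
    kappa = contact.on_grid(f_S.grid)
    force = float((kappa * f_I.values).sum() * f_S.grid.cell_area)
    return DensityField2D(f_S.grid, f_S.values * force)


def epidemic_exchange_step(
    fields: CompartmentFields, params: EpidemicParams, dt: float,
    contact: ContactFunction | None = None,
) -> CompartmentFields:
    """Explicit Euler step of the cellwise compartment exchange.

    Reaction terms: S: -K + (1-alpha) gamma f_I;  E: +K - zeta f_E;
    I: (1-eta) zeta f_E - gamma f_I;  R: eta zeta f_E + alpha gamma f_I.
    They telescope, so total mass is conserved exactly.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    contact = contact or ContactFunction(beta=params.beta)
    k_field = incidence_operator(fields.f_S, fields.f_I, contact).values
    fs, fe, fi, fr = (fields.f_S.values, fields.f_E.values, fields.f_I.values, fields.f_R.values)
    latency = params.zeta * fe
    recovery = params.gamma * fi
    new_s = fs + dt * (-k_field + (1.0 - params.alpha) * recovery)
    new_e = fe + dt * (k_field - latency)
    new_i = fi + dt * ((1.0 - params.eta) * latency - recovery)
    new_r = fr + dt * (params.eta * latency + params.alpha * recovery)
    for name, arr in (("S", new_s), ("E", new_e), ("I", new_i), ("R", new_r)):
        if np.any(arr < -1e-12):
            raise RuntimeError(
                f"exchange step drove compartment {name} negative; decrease dt"
            )
    grid = fields.grid
    return CompartmentFields(
        DensityField2D(grid, np.maximum(new_s, 0.0)),
        DensityField2D(grid, np.maximum(new_e, 0.0)),
        DensityField2D(grid, np.maximum(new_i, 0.0)),
        DensityField2D(grid, np.maximum(new_r, 0.0)),
    )


@dataclass
class MomentTrajectory:
    """Masses and means per compartment plus global means, over time."""

    times: np.ndarray  # (T,)
    masses: np.ndarray  # (T, 4) ordered S, E, I, R
    means_plus: np.ndarray  # (T, 4) per-compartment m_J+
    means_minus: np.ndarray  # (T, 4)
    m_plus: np.ndarray  # (T,) global
    m_minus: np.ndarray  # (T,)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for k, t in enumerate(self.times):
            for j, comp in enumerate(COMPARTMENTS):
                rows.append(
                    {
                        "time": t,
                        "compartment": comp,
                        "mass": self.masses[k, j],
                        "m_plus": self.means_plus[k, j],
                        "m_minus": self.means_minus[k, j],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class CoupledResult:
    times: np.ndarray
    fields: list[CompartmentFields]
    field_times: np.ndarray
    moments: MomentTrajectory


def _compartment_moments(fields: CompartmentFields) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    grid = fields.grid
    cp = grid.axis_plus.centers
    cm = grid.axis_minus.centers
    masses = np.empty(4)
    mp = np.full(4, np.nan)
    mm = np.full(4, np.nan)
    for j, comp in enumerate(COMPARTMENTS):
        v = fields.as_dict()[comp].values
        rho = v.sum() * grid.cell_area
        masses[j] = rho
        if rho > 1e-300:
            mp[j] = (v.sum(axis=1) * cp).sum() * grid.cell_area / rho
            mm[j] = (v.sum(axis=0) * cm).sum() * grid.cell_area / rho
    return masses, mp, mm


def solve_coupled(
    init: CompartmentFields,
    opinion_params: dict[str, OpinionParams],
    epidemic_params: EpidemicParams,
    t_final: float,
    dt: float | None = None,
    contact: ContactFunction | None = None,
    store_times: np.ndarray | None = None,
) -> CoupledResult:
    """Advance the coupled kinetic system by splitting: F+, F-, exchange.

    ``opinion_params`` maps compartment letters to their opinion rates; the
    drift in every compartment targets the global means, recomputed after each
    substep.  Moments are recorded every step, full field sets at
    ``store_times``.
    """
    grid = init.grid
    if dt is None:
        dt = grid.dw_plus
    n_steps = int(round(t_final / dt))
    if store_times is None:
        store_times = np.array([0.0, t_final])
    store_steps = set(
        int(s) for s in np.clip(np.round(np.asarray(store_times, float) / dt), 0, n_steps).astype(int)
    )
    contact = contact or ContactFunction(beta=epidemic_params.beta)

    state = init.copy()
    T = n_steps + 1
    times = np.arange(T) * dt
    masses = np.empty((T, 4))
    means_p = np.empty((T, 4))
    means_m = np.empty((T, 4))
    g_plus = np.empty(T)
    g_minus = np.empty(T)
    stored: dict[int, CompartmentFields] = {}

    def record(k: int) -> None:
        masses[k], means_p[k], means_m[k] = _compartment_moments(state)
        g_plus[k], g_minus[k] = state.global_means()
        if k in store_steps:
            stored[k] = state.copy()

    record(0)
    for k in range(1, T):
        # w+ sweeps, drift toward the current global mean m+
        m_plus = state.total_marginal_plus().normalized().mean
        new = {}
        for comp, f in state.as_dict().items():
            p = opinion_params[comp]
            coeffs = scheme_coefficients(
                grid.axis_plus, p.lambda_plus, p.sigma_plus, m_plus, p.diffusion_kind
            )
            new[comp] = fp_sweep_1d(f.values.T, coeffs, dt).T
        state = CompartmentFields(*(DensityField2D(grid, new[c]) for c in COMPARTMENTS))
        # w- sweeps, drift toward the recomputed global mean m-
        m_minus = state.total_marginal_minus().normalized().mean
        new = {}
        for comp, f in state.as_dict().items():
            p = opinion_params[comp]
            coeffs = scheme_coefficients(
                grid.axis_minus, p.lambda_minus, p.sigma_minus, m_minus, p.diffusion_kind
            )
            new[comp] = fp_sweep_1d(f.values, coeffs, dt)
        state = CompartmentFields(*(DensityField2D(grid, new[c]) for c in COMPARTMENTS))
        # compartment exchange
        state = epidemic_exchange_step(state, epidemic_params, dt, contact)
        record(k)

    keys = sorted(stored)
    return CoupledResult(
        times=times,
        fields=[stored[s] for s in keys],
        field_times=np.array([s * dt for s in keys]),
        moments=MomentTrajectory(times, masses, means_p, means_m, g_plus, g_minus),
    )


def moment_ode_oracle(
    epidemic_params: EpidemicParams,
    opinion_params: dict[str, OpinionParams],
    init_masses: CompartmentMasses,
    init_means_plus: np.ndarray,
    init_means_minus: np.ndarray,
    t_final: float,
    times: np.ndarray | None = None,
    e_loss_with_mean: bool = True,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> MomentTrajectory:
    """Integrate the closed ODE system for (rho_J, rho_J m_J±), constant kappa.

    Valid for a constant contact function and product diffusivity (so the
    diffusion contributes nothing to first moments).  The exposed
    compartment's first-moment loss term is -zeta rho_E m_E± (dimensional
    consistency; set ``e_loss_with_mean=False`` for the uncorrected variant
    that drops the m_E factor).
    """
    lam_p = np.array([opinion_params[c].lambda_plus for c in COMPARTMENTS])
    lam_m = np.array([opinion_params[c].lambda_minus for c in COMPARTMENTS])
    beta, zeta, gamma = epidemic_params.beta, epidemic_params.zeta, epidemic_params.gamma
    alpha, eta = epidemic_params.alpha, epidemic_params.eta

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        rho = y[:4]
        q_p = y[4:8]  # rho_J * m_J+
        q_m = y[8:12]
        total = rho.sum()
        m_p = q_p.sum() / total
        m_m = q_m.sum() / total
        incidence = beta * rho[0] * rho[2]
        drho = np.array(
            [
                -incidence + (1.0 - alpha) * gamma * rho[2],
                incidence - zeta * rho[1],
                (1.0 - eta) * zeta * rho[1] - gamma * rho[2],
                eta * zeta * rho[1] + alpha * gamma * rho[2],
            ]
        )

        def moment_rhs(q: np.ndarray, lam: np.ndarray, m_glob: float) -> np.ndarray:
            # incidence moves S-mass carrying the S mean; latency/recovery likewise
            inc_q = beta * rho[2] * q[0]
            lat_q = zeta * q[1] if e_loss_with_mean else zeta * rho[1]
            rec_q = gamma * q[2]
            flow = np.array(
                [
                    -inc_q + (1.0 - alpha) * rec_q,
                    inc_q - lat_q,
                    (1.0 - eta) * (zeta * q[1]) - rec_q,
                    eta * (zeta * q[1]) + alpha * rec_q,
                ]
            )
            relax = -lam * (q - rho * m_glob)
            return flow + relax

        return np.concatenate([drho, moment_rhs(q_p, lam_p, m_p), moment_rhs(q_m, lam_m, m_m)])

    rho0 = init_masses.as_array()
    y0 = np.concatenate([rho0, rho0 * init_means_plus, rho0 * init_means_minus])
    if times is None:
        times = np.linspace(0.0, t_final, 201)
    sol = solve_ivp(rhs, (0.0, t_final), y0, t_eval=times, rtol=rtol, atol=atol, method="RK45")
    if not sol.success:
        raise RuntimeError(f"moment ODE integration failed: {sol.message}")
    rho = sol.y[:4].T
    with np.errstate(divide="ignore", invalid="ignore"):
        mp = np.where(rho > 1e-300, sol.y[4:8].T / rho, np.nan)
        mm = np.where(rho > 1e-300, sol.y[8:12].T / rho, np.nan)
    return MomentTrajectory(
        times=sol.t,
        masses=rho,
        means_plus=mp,
        means_minus=mm,
        m_plus=sol.y[4:8].T.sum(axis=1) / rho.sum(axis=1),
        m_minus=sol.y[8:12].T.sum(axis=1) / rho.sum(axis=1),
    )
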