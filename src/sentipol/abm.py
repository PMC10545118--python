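"""N-agent stochastic opinion dynamics (Euler-Maruyama).

Each agent carries a score pair (W+, W-) in [0,1]^2 and, per axis, relaxes
toward the opinions of the agents within its confidence radius delta while
being perturbed by multiplicative noise:

    dW_i = (1/N) sum_j Lambda(|W_i - W_j| <= delta) (W_j - W_i) dt
           + sigma s(W_i) dB_i,

with noise amplitude s(w) = sqrt(w(1-w)) ("product" diffusivity, vanishing at
both extremes) or s(w) = |w - m| ("distance").  With delta = 1 the pair sum
collapses to relaxation toward the population mean, which is the regime whose
mean-field limit is the nonlinear Fokker-Planck equation solved in
:mod:`sentipol.meanfield_fp`; the amplitude convention here matches that
solver's diffusion operator (sigma^2/2) d^2[s(w)^2 f].

Opinions are projected back onto [0,1]^2 after every step.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import OpinionParams

__all__ = ["AgentOpinions", "MomentState", "ABMTrajectory", "simulate_agents", "population_moments"]


@dataclass
class AgentOpinions:
    """Opinion state of N agents: array of shape (N, 2), columns (W+, W-)."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 2 or self.w.shape[1] != 2 or self.w.shape[0] < 1:
            raise ValueError("opinions must be an (N, 2) array with N >= 1")
        if np.any((self.w < 0.0) | (self.w > 1.0)):
            raise ValueError("opinions must lie in [0, 1]^2")

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @classmethod
    def uniform(cls, n: int, seed: int = 0) -> "AgentOpinions":
        return cls(np.random.default_rng(seed).random((n, 2)))


@dataclass(frozen=True)
class MomentState:
    """Population means and variances per score axis."""

    m_plus: float
    m_minus: float
    v_plus: float
    v_minus: float


@dataclass
class ABMTrajectory:
    times: np.ndarray  # (T,)
    opinions: np.ndarray  # (T, N, 2)

    def moments(self) -> list[MomentState]:
        return [population_moments(AgentOpinions(w)) for w in self.opinions]


def population_moments(agents: AgentOpinions) -> MomentState:
    """Arithmetic means and population variances of the two score components."""
    m = agents.w.mean(axis=0)
    v = agents.w.var(axis=0)
    return MomentState(float(m[0]), float(m[1]), float(v[0]), float(v[1]))


def _drift(w: np.ndarray, lam: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Bounded-confidence interaction drift, per component."""
    n = w.shape[0]
    out = np.empty_like(w)
    for c in range(2):
        if delta[c] >= 1.0:
            # every pair interacts: (1/N) sum_j (W_j - W_i) = M - W_i, exactly
            out[:, c] = lam[c] * (w[:, c].mean() - w[:, c])
        else:
            diff = w[:, c][None, :] - w[:, c][:, None]  # (i, j) -> W_j - W_i
            mask = np.abs(diff) <= delta[c]
            out[:, c] = lam[c] * (diff * mask).sum(axis=1) / n
    return out


def _noise_amplitude(w: np.ndarray, kind: str) -> np.ndarray:
    if kind == "product":
        return np.sqrt(w * (1.0 - w))
    # distance: |w - m| with the current population mean
    return np.abs(w - w.mean(axis=0, keepdims=True))


def simulate_agents(
    params: OpinionParams,
    init: AgentOpinions,
    t_final: float,
    dt: float,
    seed: int,
    store_times: np.ndarray | None = None,
) -> ABMTrajectory:
    """Euler-Maruyama integration of the N-agent system.

    Snapshots are stored at the requested times (nearest time-step matching;
    defaults to initial and final state only).  Independent standard-normal
    increments are drawn per agent, component and step; the state is clamped
    to [0,1]^2 after every step.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    if t_final < 0.0:
        raise ValueError("t_final must be nonnegative")
    n_steps = int(round(t_final / dt))
    if store_times is None:
        store_times = np.array([0.0, t_final])
    store_steps = set(
        int(s)
        for s in np.clip(np.round(np.asarray(store_times, float) / dt).astype(int), 0, n_steps)
    )

    rng = np.random.default_rng(seed)
    lam = np.array([params.lambda_plus, params.lambda_minus])
    sigma = np.array([params.sigma_plus, params.sigma_minus])
    delta = np.array([params.delta_plus, params.delta_minus])
    sqrt_dt = np.sqrt(dt)

    w = init.w.copy()
    stored = {}
    if 0 in store_steps:
        stored[0] = w.copy()
    for step in range(1, n_steps + 1):
        xi = rng.standard_normal(w.shape)
        amp = _noise_amplitude(w, params.diffusion_kind)
        w = w + _drift(w, lam, delta) * dt + sigma * amp * sqrt_dt * xi
        np.clip(w, 0.0, 1.0, out=w)
        if step in store_steps:
            stored[step] = w.copy()
    steps_sorted = sorted(stored)
    return ABMTrajectory(
        times=np.array([s * dt for s in steps_sorted]),
        opinions=np.stack([stored[s] for s in steps_sorted]),
    )
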