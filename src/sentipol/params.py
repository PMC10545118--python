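"""Parameter containers for the opinion dynamics.

The bivariate opinion model is parameterized per axis (positive / negative
score) by a compromise rate ``lambda`` (1/day), a noise strength ``sigma``,
a bounded-confidence radius ``delta`` in [0, 1], and the choice of the local
diffusivity profile.

Diffusivity convention
----------------------
The agent SDE reads ``dW = lambda (m - W) dt + sigma s(W) dB`` and its
mean-field Fokker-Planck limit carries the diffusion term
``(sigma^2/2) d^2/dw^2 [ s(w)^2 f ]``.  The package works with the *squared*
amplitude (the diffusivity) ``a(w) = s(w)^2``:

* ``"product"``   — a(w) = w(1-w): self-thinking vanishes at both extremes;
  the stationary marginal is a Beta distribution with shape ratio
  ``nu = sigma^2 / (2 lambda)`` (shapes ``a = m/nu``, ``b = (1-m)/nu``).
* ``"distance"``  — a(w) = (w - m)^2: self-thinking shrinks near the mean;
  the variance obeys dV/dt = (sigma^2 - 2 lambda) V and the population
  collapses onto its mean whenever 2 lambda > sigma^2.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = ["OpinionParams", "DIFFUSION_KINDS"]

DIFFUSION_KINDS = ("product", "distance")


@dataclass(frozen=True)
class OpinionParams:
    lambda_plus: float = 0.05
    lambda_minus: float = 0.05
    sigma_plus: float = 0.05
    sigma_minus: float = 0.05
    delta_plus: float = 1.0
    delta_minus: float = 1.0
    diffusion_kind: str = "product"

    def __post_init__(self) -> None:
        for name in ("lambda_plus", "lambda_minus", "sigma_plus", "sigma_minus"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("delta_plus", "delta_minus"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.diffusion_kind not in DIFFUSION_KINDS:
            raise ValueError(
                f"diffusion_kind must be one of {DIFFUSION_KINDS}, got {self.diffusion_kind!r}"
            )

    def rates(self, axis: str) -> tuple[float, float]:
        """(lambda, sigma) for axis ``"plus"`` or ``"minus"``."""
        if axis == "plus":
            return self.lambda_plus, self.sigma_plus
        if axis == "minus":
            return self.lambda_minus, self.sigma_minus
        raise ValueError(f"axis must be 'plus' or 'minus', got {axis!r}")

    def equilibrium_ratio(self, axis: str) -> float:
        """Stationary Beta shape ratio nu = sigma^2/(2 lambda) of this axis."""
        lam, sigma = self.rates(axis)
        if lam <= 0.0:
            raise ValueError("equilibrium ratio requires lambda > 0")
        return sigma * sigma / (2.0 * lam)

    @classmethod
    def from_shape_ratios(
        cls,
        lambda_plus: float,
        mu_plus: float,
        lambda_minus: float,
        mu_minus: float,
        **kwargs,
    ) -> "OpinionParams":
        """Build dynamics whose stationary Beta shape ratios are ``mu_±``.

        Keeps the given compromise rates and sets the noise strengths to
        ``sigma = sqrt(2 lambda mu)`` so that ``sigma^2/(2 lambda) = mu``.
        This is how a calibrated equilibrium mixture (which identifies only
        the ratio, not lambda and sigma separately) is turned into a
        concrete dynamical parameter set.
        """
        if mu_plus <= 0.0 or mu_minus <= 0.0:
            raise ValueError("shape ratios must be positive")
        return cls(
            lambda_plus=lambda_plus,
            lambda_minus=lambda_minus,
            sigma_plus=math.sqrt(2.0 * lambda_plus * mu_plus),
            sigma_minus=math.sqrt(2.0 * lambda_minus * mu_minus),
            **kwargs,
        )

    def with_(self, **changes) -> "OpinionParams":
        return replace(self, **changes)
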