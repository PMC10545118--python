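"""Reference calibration shipped with the package.

These values are the published equilibrium fit of the two-component Beta
mixtures to the marginal sentiment distributions of a corpus of 4077 posts
collected from six Italian vaccine-hesitant Telegram group chats (August 2021
to February 2022), together with the compartmental parameters derived from
that fit (contact rate from the final-size relation, one-day latency and
spreading times).

Each mixture component is reported as a (mean, compromise rate, noise
strength) triple; the stationary marginal identifies only the shape ratio
``mu = lambda/sigma^2`` (see :meth:`sentipol.equilibria.BetaSpec.from_rates`),
so the rates are kept verbatim and converted on demand.
"""
from __future__ import annotations

from .equilibria import BetaMixtureSpec, BetaSpec
from .params import OpinionParams
from .seir import CompartmentMasses, EpidemicParams

__all__ = [
    "CORPUS_N_POSTS",
    "CORPUS_N_CHATS",
    "CORPUS_SPAN_DAYS",
    "RHO_S_INF",
    "NEGATIVE_RATES",
    "POSITIVE_RATES",
    "negative_mixture",
    "positive_mixture",
    "epidemic_params",
    "initial_masses",
    "compartment_opinion_params",
]

CORPUS_N_POSTS = 4077
CORPUS_N_CHATS = 6
CORPUS_SPAN_DAYS = 191.0  # 2021-08-20 to 2022-02-27

#: Fitted equilibrium susceptible fraction (weight of the S component).
RHO_S_INF = 0.5188

#: Fitted (mean, lambda, sigma) per component for the negative-score marginal.
NEGATIVE_RATES = {
    "S": (0.0793, 0.0475, 0.3871),
    "R": (0.5574, 0.0063, 0.1756),
}

#: Fitted (mean, lambda, sigma) per component for the positive-score marginal.
POSITIVE_RATES = {
    "S": (0.0400, 0.0412, 0.4658),
    "R": (0.1375, 0.0126, 0.3228),
}

#: Calibrated contact rate (per day) from inverting the final-size relation.
BETA_CONTACT = 1.21


def _mixture(rates: dict[str, tuple[float, float, float]]) -> BetaMixtureSpec:
    return BetaMixtureSpec(
        weight_S=RHO_S_INF,
        spec_S=BetaSpec.from_rates(*rates["S"]),
        spec_R=BetaSpec.from_rates(*rates["R"]),
    )


def negative_mixture() -> BetaMixtureSpec:
    """Calibrated stationary mixture of the negative-score marginal (bimodal)."""
    return _mixture(NEGATIVE_RATES)


def positive_mixture() -> BetaMixtureSpec:
    """Calibrated stationary mixture of the positive-score marginal (unimodal)."""
    return _mixture(POSITIVE_RATES)


def epidemic_params() -> EpidemicParams:
    """Calibrated compartment rates: beta = 1.21/day, one-day latency and spreading."""
    return EpidemicParams(beta=BETA_CONTACT, zeta=1.0, gamma=1.0, alpha=1.0, eta=0.0)


def initial_masses() -> CompartmentMasses:
    """Initial compartment split used in the calibration runs."""
    return CompartmentMasses(0.9, 0.05, 0.025, 0.025)


def compartment_opinion_params() -> dict[str, OpinionParams]:
    """Per-compartment opinion dynamics matching the calibrated equilibria.

    S, E and I carry the susceptible-component rates (E and I hold vanishing
    mass at equilibrium, so the stationary marginals are unaffected by this
    choice); R carries the recovered-component rates.  Noise strengths are set
    so that the dynamical equilibrium shape ratios equal the calibrated
    ``mu = lambda/sigma^2`` of each component.
    """
    out: dict[str, OpinionParams] = {}
    for comp in ("S", "E", "I", "R"):
        key = "R" if comp == "R" else "S"
        m_p, lam_p, sig_p = POSITIVE_RATES[key]
        m_n, lam_n, sig_n = NEGATIVE_RATES[key]
        out[comp] = OpinionParams.from_shape_ratios(
            lambda_plus=lam_p,
            mu_plus=lam_p / sig_p**2,
            lambda_minus=lam_n,
            mu_minus=lam_n / sig_n**2,
        )
    return out
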