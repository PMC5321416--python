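"""The Bayesian observer: Gaussian prior-likelihood fusion over perceived pain.

Perceived pain P given treatment condition C and stimulation S is

    Pr(P | C, S)  ∝  Pr(P | C) x Pr(S | P)

with a condition-specific Gaussian prior Pr(P|C) = N(mu_prior, sigma_prior)
learned during conditioning, and a Gaussian sensory likelihood
Pr(S|P) = N(mu_s(weight), sigma_s) whose mean follows the logarithmic
psychophysical map.  The posterior is again Gaussian with

    1/sigma_post^2 = 1/sigma_prior^2 + 1/sigma_s^2
    mu_post        = sigma_post^2 * (mu_prior/sigma_prior^2 + mu_s/sigma_s^2)

i.e. the precision-weighted mean.  The posterior mean is the model's point
prediction of the reported pain rating; the posterior is not truncated at 0
(ratings are magnitude estimates, unbounded above, and the plain-Gaussian
form is kept exact).

A flat (improper, infinite-sigma) belief is allowed on at most one side of
the fusion; it acts as the identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .psychophys import PsychMap, sensation_mean


class UndefinedPosteriorError(ValueError):
    """Both beliefs are flat: the posterior is improper."""


@dataclass(frozen=True)
class GaussianBelief:
    """A (mean, sd) pair playing the role of prior, likelihood or posterior."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    @property
    def is_flat(self) -> bool:
        return math.isinf(self.sigma)

    @property
    def precision(self) -> float:
        return 0.0 if self.is_flat else 1.0 / self.sigma**2


#: Improper flat belief; usable as the control-condition prior.
FLAT = GaussianBelief(mu=0.0, sigma=math.inf)


@dataclass(frozen=True)
class ObserverParams:
    """Per participant x condition parameter bundle: prior, sensory noise, map."""

    prior: GaussianBelief
    sensory_sigma: float
    map: PsychMap

    def __post_init__(self) -> None:
        if not self.sensory_sigma > 0:
            raise ValueError("sensory_sigma must be > 0")


def fuse(prior: GaussianBelief, likelihood: GaussianBelief) -> GaussianBelief:
    """Precision-weighted Gaussian fusion of two beliefs (symmetric)."""
    if prior.is_flat and likelihood.is_flat:
        raise UndefinedPosteriorError("cannot fuse two flat beliefs")
    if prior.is_flat:
        return likelihood
    if likelihood.is_flat:
        return prior
    prec = prior.precision + likelihood.precision
    mu = (prior.mu * prior.precision + likelihood.mu * likelihood.precision) / prec
    return GaussianBelief(mu=mu, sigma=math.sqrt(1.0 / prec))


def predict_rating(params: ObserverParams, weight: float) -> GaussianBelief:
    """Posterior belief over the pain rating at ``weight`` mN.

    The ``mu`` of the returned belief is the point prediction; ``sigma``
    is the predictive spread.
    """
    likelihood = GaussianBelief(
        mu=sensation_mean(weight, params.map), sigma=params.sensory_sigma
    )
    return fuse(params.prior, likelihood)
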