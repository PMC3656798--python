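"""Predictive densities of observations with the component mean integrated out.

For the conjugate pair ``g | theta ~ N(theta, sigma2)``,
``theta ~ N(m0, s02)``, conditioning on a multiset S of observations
already assigned to a dish gives the posterior

    theta | S ~ N(mu_n, v_n),   1/v_n = 1/s02 + n/sigma2,
    mu_n = v_n * (m0/s02 + sum(S)/sigma2),

and the dish-conditional predictive of a new observation is
``N(mu_n, v_n + sigma2)``.  With S empty this is the prior predictive
``N(m0, s02 + sigma2)``.  The closed form is the production path; adaptive
quadrature and Monte-Carlo integration are kept as independent oracles.

Everything is computed in log space internally; only the public boundary
exponentiates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import integrate, stats

from .core import ObservationModel

__all__ = [
    "PredictiveQuery",
    "prior_predictive",
    "dish_predictive",
    "log_predictive",
    "log_predictive_set",
    "quad_predictive",
    "mc_integrate",
    "MCIntegral",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PredictiveQuery:
    """A predictive evaluation: density of ``g`` given the multiset ``S`` of
    observations currently sharing its dish (``g`` excluded)."""

    g: float
    S: tuple[float, ...]
    model: ObservationModel

    def __post_init__(self) -> None:
        object.__setattr__(self, "S", tuple(float(v) for v in self.S))
        if not math.isfinite(self.g) or not all(math.isfinite(v) for v in self.S):
            raise ValueError("predictive query values must be finite")


def _posterior(n: int, total: float, model: ObservationModel) -> tuple[float, float]:
    """Posterior (mean, variance) of theta given n observations summing to total."""
    s02, sigma2, m0 = model.prior_variance, model.obs_variance, model.prior_mean
    if s02 == 0.0:
        return m0, 0.0
    prec = 1.0 / s02 + n / sigma2
    var = 1.0 / prec
    mean = var * (m0 / s02 + total / sigma2)
    return mean, var


def log_predictive(g: float, n: int, total: float, model: ObservationModel) -> float:
    """Log density of ``g`` given dish sufficient statistics (count, sum)."""
    mean, var = _posterior(n, total, model)
    pv = var + model.obs_variance
    z = g - mean
    return -0.5 * (_LOG_2PI + math.log(pv) + z * z / pv)


def log_predictive_set(values: Iterable[float], n: int, total: float,
                       model: ObservationModel) -> float:
    """Log joint predictive density of ``values`` given dish statistics
    (count, sum), via the chain rule of one-step predictives."""
    out = 0.0
    for v in values:
        out += log_predictive(v, n, total, model)
        n += 1
        total += v
    return out


def prior_predictive(g: float, model: ObservationModel) -> float:
    """Marginal density of one observation: integral of F(g|theta) dmu1."""
    if not math.isfinite(g):
        raise ValueError("g must be finite")
    return math.exp(log_predictive(g, 0, 0.0, model))


def dish_predictive(query: PredictiveQuery) -> float:
    """Conditional density of ``query.g`` given the dish's other data — the
    ratio of the with-g to without-g marginal likelihoods, in closed form."""
    n = len(query.S)
    return math.exp(log_predictive(query.g, n, math.fsum(query.S), query.model))


def quad_predictive(query: PredictiveQuery) -> float:
    """Quadrature oracle for :func:`dish_predictive`: evaluates the ratio of
    the two theta-integrals numerically on ``m0 +/- 12`` combined SD.

    Test oracle only — slower and less robust than the closed form for
    large conditioning sets.
    """
    model = query.model
    if model.prior_variance == 0.0:
        return math.exp(log_predictive(query.g, len(query.S),
                                       math.fsum(query.S), model))
    sd = math.sqrt(model.obs_variance + model.prior_variance)
    lo, hi = model.prior_mean - 12 * sd, model.prior_mean + 12 * sd
    obs_sd = math.sqrt(model.obs_variance)
    prior = stats.norm(model.prior_mean, math.sqrt(model.prior_variance))

    def density_product(theta: float, values: tuple[float, ...]) -> float:
        out = prior.pdf(theta)
        for v in values:
            out *= stats.norm.pdf(v, loc=theta, scale=obs_sd)
        return out

    num, _ = integrate.quad(density_product, lo, hi,
                            args=((query.g,) + query.S,), limit=200)
    if not query.S:
        return num
    den, _ = integrate.quad(density_product, lo, hi, args=(query.S,), limit=200)
    return num / den


@dataclass(frozen=True)
class MCIntegral:
    """Monte-Carlo estimate of the predictive ratio: numerator and
    denominator integrals with standard errors, and their ratio."""

    numerator: float
    numerator_se: float
    denominator: float
    denominator_se: float

    @property
    def ratio(self) -> float:
        return self.numerator / self.denominator


def mc_integrate(g: float, S: Iterable[float], model: ObservationModel,
                 n_draws: int = 100_000, seed: int | None = None) -> MCIntegral:
    """Monte-Carlo oracle: draws theta from the base measure and averages the
    product of observation densities, for both the with-g (numerator) and
    without-g (denominator) integrals of the predictive ratio."""
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    S = tuple(float(v) for v in S)
    rng = np.random.default_rng(seed)
    if model.prior_variance == 0.0:
        theta = np.full(n_draws, model.prior_mean)
    else:
        theta = rng.normal(model.prior_mean, math.sqrt(model.prior_variance),
                           size=n_draws)
    obs_sd = math.sqrt(model.obs_variance)

    def averaged(values: tuple[float, ...]) -> tuple[float, float]:
        prod = np.ones(n_draws)
        for v in values:
            prod *= stats.norm.pdf(v, loc=theta, scale=obs_sd)
        est = float(prod.mean())
        se = float(prod.std(ddof=1) / math.sqrt(n_draws))
        return est, se

    num, num_se = averaged((g,) + S)
    den, den_se = averaged(S) if S else (1.0, 0.0)
    return MCIntegral(num, num_se, den, den_se)
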