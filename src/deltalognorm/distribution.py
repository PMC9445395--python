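"""The delta-lognormal (zero-inflated lognormal) distribution.

A nonnegative variable y follows the delta-lognormal distribution when it
equals zero with probability p0 and otherwise is lognormal:

    g(y; p0, mu, sigma2) = p0 * delta(y) + (1 - p0) * f(y; mu, sigma2)

with delta a unit point mass at zero and f the lognormal density with
log-scale location mu and log-scale variance sigma2.  Writing

    alpha = exp(mu + sigma2 / 2),   beta = exp(sigma2),

the first three cumulants are

    kappa1 = (1 - p0) alpha
    kappa2 = (1 - p0) alpha^2 (beta - (1 - p0))
    kappa3 = (1 - p0) alpha^3 (beta^3 - 3 (1 - p0) beta + 2 (1 - p0)^2)

and the skewness is gamma1 = kappa3 / kappa2^{3/2}.  This module provides
the density, the cumulants and a reproducible sampler; the sampler is the
synthetic-data generator for the whole package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri
from scipy.stats import lognorm

__all__ = ["ModelParams", "Cumulants", "mixture_density", "cumulants", "sample"]


@dataclass(frozen=True)
class ModelParams:
    """Superpopulation parameter triple (p0, mu, sigma2).

    Parameters
    ----------
    p0 : float
        Probability of a zero value, in [0, 1].  p0 = 1 is admitted only
        for degenerate cumulant checks; estimation requires p0 < 1.
    mu : float
        Lognormal log-scale location.
    sigma2 : float
        Lognormal log-scale variance, nonnegative (0 only in limit checks).
    """

    p0: float
    mu: float
    sigma2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p0 <= 1.0):
            raise ValueError(f"p0 must be in [0, 1], got {self.p0}")
        if self.sigma2 < 0:
            raise ValueError(f"sigma2 must be nonnegative, got {self.sigma2}")
        if not math.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu}")

    @classmethod
    def from_sigma(cls, p0: float, mu: float, sigma: float) -> "ModelParams":
        """Construct from the log-scale standard deviation sigma."""
        return cls(p0=p0, mu=mu, sigma2=sigma * sigma)

    @property
    def sigma(self) -> float:
        return math.sqrt(self.sigma2)

    @property
    def alpha(self) -> float:
        """Mean of the positive (lognormal) part, exp(mu + sigma2/2)."""
        return math.exp(self.mu + 0.5 * self.sigma2)

    @property
    def beta(self) -> float:
        """exp(sigma2)."""
        return math.exp(self.sigma2)


@dataclass(frozen=True)
class Cumulants:
    """First three cumulants and the skewness of the mixture."""

    kappa1: float
    kappa2: float
    kappa3: float
    gamma1: float  # NaN when kappa2 == 0 (degenerate parameters)


def mixture_density(y: float, params: ModelParams) -> tuple[float, float]:
    """Point mass and density of the mixture at y.

    Returns ``(p0, 0.0)`` at y = 0 and ``(0.0, (1 - p0) f(y))`` at y > 0,
    with f the lognormal density.  The continuous part integrates to 1 - p0.
    """
    if y < 0:
        raise ValueError(f"y must be nonnegative, got {y}")
    if y == 0.0:
        return params.p0, 0.0
    dens = (1.0 - params.p0) * lognorm.pdf(
        y, s=params.sigma, scale=math.exp(params.mu)
    )
    return 0.0, float(dens)


def cumulants(params: ModelParams) -> Cumulants:
    """Mean, variance, third central moment and skewness of the mixture."""
    p0 = params.p0
    q = 1.0 - p0
    a = params.alpha
    b = params.beta
    k1 = q * a
    k2 = q * a * a * (b - q)
    k3 = q * a**3 * (b**3 - 3.0 * q * b + 2.0 * q * q)
    gamma1 = k3 / k2**1.5 if k2 > 0 else float("nan")
    return Cumulants(kappa1=k1, kappa2=k2, kappa3=k3, gamma1=gamma1)


def _draw(params: ModelParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Core sampler: n values from one (uniform, uniform) pair per unit.

    Each unit consumes exactly two consecutive uniforms from the stream
    (zero indicator, then normal deviate via the inverse CDF), so a fixed
    seed reproduces any prefix of the sample and the vectorised Monte-Carlo
    engine consumes the stream identically to repeated calls of this
    function.
    """
    u = rng.random((n, 2))
    zero = u[:, 0] < params.p0
    logs = params.mu + params.sigma * ndtri(u[:, 1])
    y = np.exp(logs)
    y[zero] = 0.0
    return y


def sample(
    params: ModelParams,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw n independent delta-lognormal values.

    Each value is 0 with probability p0 and otherwise exp(mu + sigma * Z)
    with Z standard normal.  Zeros are exact (== 0.0).

    Parameters
    ----------
    params : ModelParams
    n : int
        Sample size, >= 1.
    seed : int, numpy Generator or None
        Seed (or a Generator to draw from an existing stream).
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _draw(params, n, rng)
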