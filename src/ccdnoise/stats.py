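"""Probability primitives for mixed Poisson--Gaussian detector noise.

Counts produced by a scintillation-coupled CCD are not true-Poisson: every
beam electron is converted into a cloud of secondary quanta, so the recorded
counts behave like a Poisson variable scaled by the composite detector gain
``g`` (variance ``g`` times the mean).  This module collects the small
distribution algebra the rest of the package is written against:

* the scaled ("super/sub") Poisson distribution with gain ``g``,
* the Skellam distribution of a difference of two Poisson variables
  (what dark-frame subtraction leaves of the thermal noise),
* moment rules for products and reciprocals of Gaussian variables
  (what gain-reference multiplication does to the noise).

All pmfs are evaluated on the integer count grid; for fractional ``g`` the
scaled-Poisson expression is a density approximation and is renormalized
numerically over the grid so the masses sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy import stats as sps

__all__ = [
    "GaussianParams",
    "ScaledPoissonParams",
    "SkellamParams",
    "scaled_poisson_pmf",
    "scaled_poisson_sample",
    "skellam_pmf",
    "skellam_sample",
    "gaussian_product_moments",
    "inverse_gaussian_approx",
]


@dataclass(frozen=True)
class GaussianParams:
    """Mean/variance summary of a Gaussian variable, in counts and counts^2."""

    mu: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError(f"variance must be >= 0, got {self.sigma2}")


@dataclass(frozen=True)
class ScaledPoissonParams:
    """Scaled Poisson: mean ``s_hat`` counts, variance ``g * s_hat``.

    ``g`` is the counts produced per primary event; ``g > 1`` is
    super-Poisson, ``g < 1`` sub-Poisson, ``g = 1`` true Poisson.
    """

    s_hat: float
    g: float

    def __post_init__(self) -> None:
        if self.s_hat < 0:
            raise ValueError(f"expected counts must be >= 0, got {self.s_hat}")
        if self.g <= 0:
            raise ValueError(f"gain must be > 0, got {self.g}")

    @property
    def mean(self) -> float:
        return self.s_hat

    @property
    def variance(self) -> float:
        return self.g * self.s_hat


@dataclass(frozen=True)
class SkellamParams:
    """Difference of two Poisson variables with means ``s1`` and ``s2``."""

    s1: float
    s2: float

    def __post_init__(self) -> None:
        if self.s1 < 0 or self.s2 < 0:
            raise ValueError("Skellam means must be >= 0")

    @property
    def mean(self) -> float:
        return self.s1 - self.s2

    @property
    def variance(self) -> float:
        return self.s1 + self.s2


def _scaled_poisson_raw(s_hat: float, g: float, n: np.ndarray) -> np.ndarray:
    """Unnormalized density (g^-1 S)^(g^-1 n) / Gamma(g^-1 n + 1) exp(-g^-1 S)."""
    lam = s_hat / g
    x = np.asarray(n, dtype=float) / g
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = special.xlogy(x, lam) - special.gammaln(x + 1.0) - lam
    return np.exp(logp)


def scaled_poisson_pmf(
    params: ScaledPoissonParams,
    n,
    *,
    renormalize: bool = True,
) -> np.ndarray | float:
    """Probability mass of the scaled-Poisson distribution on the count grid.

    Parameters
    ----------
    params:
        Distribution parameters (expected counts and gain).
    n:
        Count value(s); must be non-negative.  Evaluation is on the integer
        grid ``n = 0, 1, 2, ...``; non-integer n are accepted (the formula is
        a density) but renormalization always refers to the integer grid.
    renormalize:
        Divide by the total mass on the integer grid so probabilities sum to
        one.  With fractional ``g`` the raw expression carries a residual
        normalization of order ``g``; see the methods note.
    """
    n_arr = np.atleast_1d(np.asarray(n, dtype=float))
    if np.any(n_arr < 0):
        raise ValueError("count values must be >= 0")
    p = _scaled_poisson_raw(params.s_hat, params.g, n_arr)
    if renormalize:
        p = p / _scaled_poisson_norm(params)
    return p if np.ndim(n) else float(p[0])


def _scaled_poisson_norm(params: ScaledPoissonParams) -> float:
    """Total raw mass on the integer grid (truncated 12 sigma above the mean)."""
    hi = int(np.ceil(params.s_hat + 12.0 * np.sqrt(params.variance + 1.0) + 10.0 * params.g))
    grid = np.arange(0, hi + 1, dtype=float)
    return float(_scaled_poisson_raw(params.s_hat, params.g, grid).sum())


def scaled_poisson_sample(
    params: ScaledPoissonParams, size, rng: np.random.Generator
) -> np.ndarray:
    """Draw samples as ``g * Poisson(s_hat / g)`` (the defining construction)."""
    return params.g * rng.poisson(params.s_hat / params.g, size=size)


def skellam_pmf(params: SkellamParams, n) -> np.ndarray | float:
    """Probability that the difference of the two Poisson draws equals ``n``.

    Uses the modified-Bessel closed form through an exponentially weighted
    evaluation (no overflow at large means).  ``s2 = 0`` degenerates to the
    plain Poisson pmf in ``n``.
    """
    n_arr = np.atleast_1d(np.asarray(n))
    if not np.all(n_arr == np.round(n_arr)):
        raise ValueError("Skellam support is the integers")
    n_int = np.round(n_arr).astype(int)
    s1, s2 = params.s1, params.s2
    if s2 == 0.0:
        p = np.where(n_int >= 0, sps.poisson.pmf(np.maximum(n_int, 0), s1), 0.0)
    elif s1 == 0.0:
        p = np.where(n_int <= 0, sps.poisson.pmf(np.maximum(-n_int, 0), s2), 0.0)
    else:
        # exp{-(s1+s2)} (s1/s2)^{n/2} I_|n|(2 sqrt(s1 s2)), via ive = iv * exp(-|x|)
        x = 2.0 * np.sqrt(s1 * s2)
        logp = (
            -(s1 + s2)
            + 0.5 * n_int * (np.log(s1) - np.log(s2))
            + np.log(special.ive(np.abs(n_int), x))
            + x
        )
        p = np.exp(logp)
    return p if np.ndim(n) else float(p[0])


def skellam_sample(params: SkellamParams, size, rng: np.random.Generator) -> np.ndarray:
    return rng.poisson(params.s1, size=size) - rng.poisson(params.s2, size=size)


def gaussian_product_moments(a: GaussianParams, b: GaussianParams) -> GaussianParams:
    """Moments of the product of two independent variables.

    mean = mu_X mu_Y;  var = (sig_X^2 + mu_X^2)(sig_Y^2 + mu_Y^2) - mu_X^2 mu_Y^2.
    The product is not Gaussian in general; only the first two moments are
    propagated (which is what the noise model uses).
    """
    mu = a.mu * b.mu
    var = (a.sigma2 + a.mu**2) * (b.sigma2 + b.mu**2) - a.mu**2 * b.mu**2
    return GaussianParams(mu, var)


def inverse_gaussian_approx(a: GaussianParams) -> GaussianParams:
    """Gaussian approximation of the reciprocal 1/X for X ~ N(mu, sigma^2).

    Valid when the denominator is narrowly distributed about its mean
    (mu >> sigma); returns N(1/mu, sigma^2 / mu^4).
    """
    if a.mu == 0:
        raise ValueError("reciprocal of a zero-mean Gaussian is undefined")
    sigma = np.sqrt(a.sigma2)
    if sigma > 0 and abs(a.mu) / sigma < 10.0:
        warnings.warn(
            "inverse_gaussian_approx: mu/sigma < 10, the Gaussian "
            "approximation of the reciprocal may be poor",
            RuntimeWarning,
            stacklevel=2,
        )
    return GaussianParams(1.0 / a.mu, a.sigma2 / a.mu**4)
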