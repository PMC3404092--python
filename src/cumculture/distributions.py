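"""Skill-distribution toolkit: sampling, moments, modes and expected maxima.

Populations of social learners are modelled as i.i.d. draws of a continuous
skill value from one of three location-scale families — Gumbel (parameterized
by mode and scale), Logistic, or Normal.  The quantity that drives every model
in this package is the expected value of the *largest* skill in a sample of
size ``n``:

* Gumbel(m, beta):    ``m + beta * (euler_gamma + ln n)``  (exact)
* Logistic(mu, s):    ``mu + s * (digamma(n) + euler_gamma)``  (exact)
* Normal(mu, sigma):  ``mu + sigma * ndtri(0.5264 ** (1/n))``  (Chen–Tyler
  approximation of the order-statistic integral, accurate to well under 1%)

The exact Normal expectation is also available through numeric quadrature
(:func:`expected_max_exact_normal`) and serves as the oracle for the
approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import digamma, ndtr, ndtri

EULER_GAMMA: float = float(np.euler_gamma)

#: Chen & Tyler's constant: E[max of n iid N(0,1)] ~= ndtri(0.5264 ** (1/n)).
CHEN_TYLER_CONSTANT: float = 0.5264

FAMILIES = ("gumbel", "logistic", "normal")


@dataclass(frozen=True)
class SkillDistributionSpec:
    """Family, location and scale of a population skill distribution.

    ``location`` is the Gumbel mode ``m``, the Logistic location, or the
    Normal mean ``mu``; for the Gumbel the (mode, scale) parameterization
    coincides with the common (location, scale) convention.  The "standard
    logistic" is location 0, scale 1.
    """

    family: str
    location: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    @property
    def mean(self) -> float:
        """Theoretical population mean (Gumbel: location + euler_gamma*scale)."""
        return population_mean_theoretical(self)

    @property
    def variance(self) -> float:
        if self.family == "gumbel":
            return math.pi**2 * self.scale**2 / 6.0
        if self.family == "logistic":
            return math.pi**2 * self.scale**2 / 3.0
        return self.scale**2


@dataclass
class Population:
    """One generation's skill values."""

    values: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("a population needs at least one skill value")
        if self.generation < 0:
            raise ValueError("generation must be non-negative")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def max(self) -> float:
        return float(self.values.max())


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_population(spec: SkillDistributionSpec, n: int, rng) -> Population:
    """Draw ``n`` i.i.d. skills from ``spec``; reproducible given a seed."""
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    gen = _as_rng(rng)
    if spec.family == "gumbel":
        values = gen.gumbel(spec.location, spec.scale, size=n)
    elif spec.family == "logistic":
        values = gen.logistic(spec.location, spec.scale, size=n)
    else:
        values = gen.normal(spec.location, spec.scale, size=n)
    return Population(values=values, generation=0)


def expected_max(spec: SkillDistributionSpec, n: int) -> float:
    """Expected value of the highest of ``n`` draws from ``spec``.

    Closed form for Gumbel and Logistic; Chen–Tyler approximation for the
    Normal (see :func:`expected_max_exact_normal` for the exact integral).
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    if spec.family == "gumbel":
        return spec.location + spec.scale * (EULER_GAMMA + math.log(n))
    if spec.family == "logistic":
        return spec.location + spec.scale * (float(digamma(n)) + EULER_GAMMA)
    return spec.location + spec.scale * float(
        ndtri(CHEN_TYLER_CONSTANT ** (1.0 / n))
    )


def expected_max_exact_normal(mu: float, sigma: float, n: int) -> float:
    """Exact E[max] of ``n`` iid Normal(mu, sigma) draws by quadrature.

    Integrates the largest-order-statistic density
    ``n * phi(t) * Phi(t)**(n-1)`` over an interval that contains the
    distribution's effective support, ``[-10, 10 + ln n]`` in standard units.
    Serves as the brute-force oracle for the Chen–Tyler approximation.
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")

    inv_sqrt_2pi = 1.0 / math.sqrt(2.0 * math.pi)

    def integrand(t: float) -> float:
        phi = inv_sqrt_2pi * math.exp(-0.5 * t * t)
        return n * t * phi * ndtr(t) ** (n - 1)

    lo, hi = -10.0, 10.0 + math.log(n)
    value, err = integrate.quad(integrand, lo, hi, epsabs=1e-9, limit=400)
    if err > 1e-6:
        raise ArithmeticError(
            f"order-statistic quadrature did not converge (n={n}, "
            f"estimated error {err:.3e})"
        )
    return mu + sigma * value


def population_mean_theoretical(spec: SkillDistributionSpec) -> float:
    """Theoretical mean skill of the population distribution."""
    if spec.family == "gumbel":
        return spec.location + EULER_GAMMA * spec.scale
    # logistic and normal are symmetric about their location
    return spec.location


def matching_normal_sd(beta: float) -> float:
    """Normal sigma with the same variance as a Gumbel of scale ``beta``.

    The Gumbel variance is ``pi**2 * beta**2 / 6``, so
    ``sigma = beta * pi / sqrt(6)`` (1.28 for beta = 1, to two decimals).
    """
    if beta < 0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    return beta * math.pi / math.sqrt(6.0)


def empirical_mode(values) -> float:
    """Half-sample-mode estimate of a sample's mode.

    Recursively narrows the sorted sample to the half-width window (of
    ``ceil(k/2)`` consecutive points) with the smallest range; ties are broken
    toward the smaller values, and the two-point base case returns the smaller
    value, so the estimate is deterministic for any input.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    if x.size == 0:
        raise ValueError("empirical_mode needs at least one value")
    while x.size > 2:
        h = (x.size + 1) // 2  # half-sample window length
        widths = x[h - 1:] - x[: x.size - h + 1]
        i = int(np.argmin(widths))  # first minimum -> smaller values win ties
        x = x[i : i + h]
    return float(x[0])
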