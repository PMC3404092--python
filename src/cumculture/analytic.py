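"""Analytic skill-transmission model: Price equation, critical curves, sensitivity.

The one-generation change in mean skill when every learner copies the most
skilled individual decomposes (via the Price equation) into the gap between
the expected population maximum and the population mean, plus the mean
imitation error.  For each skill family this yields a closed form:

* Gumbel(m, beta), Gumbel error (alpha, beta):
  ``dzbar = -alpha + beta * (euler_gamma + ln N)``
* standard Logistic scale s, transmission inaccuracy I:
  ``dzbar = s * (digamma(N) + euler_gamma) - I``
* Normal sd sigma, Normal error (alpha_N, sigma_e):
  ``dzbar = sigma * ndtri(0.5264 ** (1/N)) - alpha_N``

Setting ``dzbar = 0`` defines the critical relationship between population
size ``N`` and the maximum sustainable skill complexity.  Complexity is
measured as transmission inaccuracy (the Gumbel curve is conventionally
reported in ``alpha``, whose error mean is ``-alpha + euler_gamma * beta``).
The derivative of the critical curve with respect to ``N`` measures how
sensitive a population's sustainable complexity is to demographic change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, ndtri, polygamma

from .distributions import CHEN_TYLER_CONSTANT, EULER_GAMMA, FAMILIES

ERROR_FAMILIES = ("gumbel", "normal")

#: skill family -> required error family (the Logistic variant keeps the
#: Gumbel-style error of the original model)
_ERROR_FOR_SKILL = {"gumbel": "gumbel", "logistic": "gumbel", "normal": "normal"}


@dataclass(frozen=True)
class ErrorSpec:
    """Transmission-error model: inaccuracy offset ``alpha`` and spread.

    A learner copying a mentor of skill ``z`` realizes a draw from the error
    family located at ``z - alpha``: Gumbel(mode z - alpha, scale spread) or
    Normal(mean z - alpha, sd spread).  ``alpha`` is the inaccuracy offset
    (Gumbel ``alpha`` / Normal ``alpha_N``).
    """

    family: str
    alpha: float
    spread: float

    def __post_init__(self) -> None:
        if self.family not in ERROR_FAMILIES:
            raise ValueError(
                f"unknown error family {self.family!r}; expected one of "
                f"{ERROR_FAMILIES}"
            )
        if self.alpha < 0:
            raise ValueError(f"alpha must be non-negative, got {self.alpha}")
        if not self.spread > 0:
            raise ValueError(f"spread must be positive, got {self.spread}")

    @property
    def mean(self) -> float:
        """Expected imitation error relative to the mentor's skill.

        Gumbel: ``-alpha + euler_gamma * spread``; Normal: ``-alpha``.
        """
        if self.family == "gumbel":
            return -self.alpha + EULER_GAMMA * self.spread
        return -self.alpha

    @property
    def inaccuracy(self) -> float:
        """Transmission inaccuracy: the magnitude of the mean error."""
        return -self.mean


@dataclass(frozen=True)
class CriticalCurve:
    """Grid of (N, maximum sustainable complexity) pairs for one family."""

    n: np.ndarray
    alpha_star: np.ndarray
    family: str
    scale: float
    source: str = "analytic"  # "analytic" or "abm"

    def __post_init__(self) -> None:
        n = np.asarray(self.n, dtype=int)
        a = np.asarray(self.alpha_star, dtype=float)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "alpha_star", a)
        if n.size != a.size:
            raise ValueError("n and alpha_star must have the same length")
        if n.size and np.any(np.diff(n) <= 0):
            raise ValueError("n must be strictly increasing")
        if self.source == "analytic" and n.size and np.any(np.diff(a) <= 0):
            raise ValueError("analytic alpha_star must be strictly increasing")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": self.family,
                "scale": self.scale,
                "N": self.n,
                "alpha_star": self.alpha_star,
                "source": self.source,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def price_delta_zbar(z: Sequence[float], c: Sequence[float], dz: Sequence[float]) -> float:
    """Price-equation change in mean skill.

    ``c`` holds non-negative copying likelihoods, ``dz`` the transmission
    change incurred when the corresponding individual is copied.  Returns
    ``Cov(c, z)/cbar + E(c*dz)/cbar``.
    """
    z = np.asarray(z, dtype=float)
    c = np.asarray(c, dtype=float)
    dz = np.asarray(dz, dtype=float)
    if not (z.size == c.size == dz.size) or z.size < 1:
        raise ValueError("z, c and dz must be equal-length, non-empty")
    if np.any(c < 0):
        raise ValueError("copying likelihoods must be non-negative")
    cbar = c.mean()
    if cbar <= 0:
        raise ValueError("degenerate selection: all copying likelihoods are zero")
    cov = float(np.mean(c * z) - cbar * z.mean())
    return cov / cbar + float(np.mean(c * dz)) / cbar


def _check_n(n) -> None:
    if np.any(np.asarray(n) < 1):
        raise ValueError("population size must be >= 1")


def delta_zbar(family: str, n: int, error: ErrorSpec, skill_scale: float = 1.0) -> float:
    """Expected one-generation change in mean skill under copy-the-best.

    Positive values mean cumulation, negative values cultural loss.  The
    skill family and error family must be consistent (Gumbel and Logistic
    skills take a Gumbel error, Normal skills a Normal error).
    """
    _check_n(n)
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if not skill_scale > 0:
        raise ValueError("skill_scale must be positive")
    if error.family != _ERROR_FOR_SKILL[family]:
        raise ValueError(
            f"{family} skills require a {_ERROR_FOR_SKILL[family]} error, "
            f"got {error.family}"
        )
    gap = _max_mean_gap(family, n, skill_scale)
    return gap + error.mean


def _max_mean_gap(family: str, n, skill_scale: float):
    """E[max of N draws] - E[population mean], i.e. the selection term."""
    n = np.asarray(n, dtype=float)
    if family == "gumbel":
        gap = skill_scale * np.log(n)
    elif family == "logistic":
        gap = skill_scale * (digamma(n) + EULER_GAMMA)
    else:
        gap = skill_scale * ndtri(CHEN_TYLER_CONSTANT ** (1.0 / n))
    return gap if gap.shape else float(gap)


def critical_complexity(family: str, n, skill_scale: float = 1.0):
    """Maximum sustainable complexity at population size ``n``.

    Solves ``delta_zbar = 0`` for the complexity axis: Gumbel
    ``beta * (ln N + euler_gamma)`` (complexity as alpha, error spread equal
    to the skill scale); Logistic ``s * (digamma(N) + euler_gamma)`` and
    Normal ``sigma * ndtri(0.5264 ** (1/N))`` (complexity as transmission
    inaccuracy).  Accepts scalar or array ``n``.
    """
    _check_n(n)
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if not skill_scale > 0:
        raise ValueError("skill_scale must be positive")
    n_arr = np.asarray(n, dtype=float)
    if family == "gumbel":
        out = skill_scale * (np.log(n_arr) + EULER_GAMMA)
    elif family == "logistic":
        out = skill_scale * (digamma(n_arr) + EULER_GAMMA)
    else:
        out = skill_scale * ndtri(CHEN_TYLER_CONSTANT ** (1.0 / n_arr))
    return out if out.shape else float(out)


NOT_SUSTAINABLE = None


def critical_population_size(
    family: str, alpha: float, skill_scale: float = 1.0, n_max: int = 10**6
):
    """Smallest N (<= n_max) at which complexity ``alpha`` is sustainable.

    Returns ``None`` when even ``n_max`` individuals cannot sustain it.
    Uses integer bisection; the critical curve is strictly increasing in N.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if critical_complexity(family, n_max, skill_scale) < alpha:
        return NOT_SUSTAINABLE
    lo, hi = 1, n_max  # invariant: curve(hi) >= alpha
    if critical_complexity(family, lo, skill_scale) >= alpha:
        return 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if critical_complexity(family, mid, skill_scale) >= alpha:
            hi = mid
        else:
            lo = mid
    return hi


def sensitivity(family: str, n, skill_scale: float = 1.0):
    """Derivative of the critical curve with respect to population size.

    Gumbel: ``beta / N``; Logistic: ``s * trigamma(N)``; Normal (chain rule
    through the Chen–Tyler form with ``u = 0.5264 ** (1/N)``):
    ``sigma * u * (-ln 0.5264) / (N**2 * phi(ndtri(u)))``.  Accepts scalar or
    array ``n >= 2``.
    """
    if np.any(np.asarray(n) < 2):
        raise ValueError("sensitivity requires n >= 2")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if not skill_scale > 0:
        raise ValueError("skill_scale must be positive")
    n_arr = np.asarray(n, dtype=float)
    if family == "gumbel":
        out = skill_scale / n_arr
    elif family == "logistic":
        out = skill_scale * polygamma(1, n_arr)
    else:
        u = CHEN_TYLER_CONSTANT ** (1.0 / n_arr)
        q = ndtri(u)
        phi = np.exp(-0.5 * q * q) / math.sqrt(2.0 * math.pi)
        out = skill_scale * u * (-math.log(CHEN_TYLER_CONSTANT)) / (n_arr**2 * phi)
    return out if out.shape else float(out)


def critical_curve(family: str, n_values, skill_scale: float = 1.0) -> CriticalCurve:
    """Analytic critical curve over a grid of population sizes."""
    n = np.asarray(sorted(set(int(v) for v in np.atleast_1d(n_values))), dtype=int)
    alpha = critical_complexity(family, n, skill_scale)
    return CriticalCurve(
        n=n, alpha_star=np.atleast_1d(alpha), family=family,
        scale=skill_scale, source="analytic",
    )


def sensitivity_curve(family: str, n_values, skill_scale: float = 1.0) -> pd.DataFrame:
    """Derivative of the critical curve tabulated over ``n_values``."""
    n = np.asarray(sorted(set(int(v) for v in np.atleast_1d(n_values))), dtype=int)
    return pd.DataFrame(
        {
            "family": family,
            "scale": skill_scale,
            "N": n,
            "sensitivity": np.atleast_1d(sensitivity(family, n, skill_scale)),
        }
    )
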