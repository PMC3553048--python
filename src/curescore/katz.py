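"""Katz family of discrete distributions for the latent clonogen count.

The family is defined by the first-order recurrence on successive count
probabilities

    Pr(x + 1) / Pr(x) = (omega + theta * x) / (1 + x),   x = 0, 1, ...

with ``omega > 0`` and ``theta < 1``.  It interpolates between the
Binomial (theta < 0, under-dispersed), Poisson (theta = 0, equi-dispersed)
and Negative Binomial (theta > 0, over-dispersed) distributions while
keeping the zero-count probability

    p0 = (1 - theta)^(omega/theta)        (theta != 0)
    p0 = exp(-omega)                      (theta = 0)

as a free quantity: different dispersion regimes can share the same cure
probability p0.  The mean is omega / (1 - theta) and the dispersion index
(variance-to-mean ratio) is 1 / (1 - theta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "KatzParams",
    "validate_katz_params",
    "katz_pmf",
    "katz_log_pmf",
    "katz_pgf",
    "katz_p0",
    "katz_moments",
]

#: |theta| below this is dispatched to the exact Poisson formulas.
THETA_ZERO_TOL = 1e-10

#: relative tolerance for the integrality check of -omega/theta when theta < 0
_SUPPORT_INT_RTOL = 1e-9


@dataclass(frozen=True)
class KatzParams:
    """Parameters (omega, theta) of a Katz count distribution.

    Parameters
    ----------
    omega : float
        Positive shape parameter, equal to mean**2 / variance.
    theta : float
        Dispersion parameter, strictly less than 1.  Negative values give
        under-dispersion (Binomial-type, finite support), zero the Poisson
        distribution, positive values over-dispersion (Negative Binomial).
    """

    omega: float
    theta: float

    def __post_init__(self) -> None:
        if not (self.omega > 0 and math.isfinite(self.omega)):
            raise ValueError(f"omega must be a positive finite real, got {self.omega}")
        if not (self.theta < 1 and math.isfinite(self.theta)):
            raise ValueError(f"theta must be a finite real < 1, got {self.theta}")

    @property
    def is_poisson(self) -> bool:
        return abs(self.theta) < THETA_ZERO_TOL

    @property
    def p0(self) -> float:
        """Probability of a zero count (the cure probability)."""
        if self.is_poisson:
            return math.exp(-self.omega)
        return math.exp((self.omega / self.theta) * math.log1p(-self.theta))

    @property
    def mean(self) -> float:
        return self.omega / (1.0 - self.theta)

    @property
    def dispersion_index(self) -> float:
        """Variance-to-mean ratio, 1/(1 - theta)."""
        return 1.0 / (1.0 - self.theta)

    @property
    def variance(self) -> float:
        return self.mean * self.dispersion_index

    def finite_support_size(self) -> int | None:
        """Support upper bound N = -omega/theta for theta < 0, else None.

        Returns None when theta >= 0 (infinite support).  Raises ValueError
        when theta < 0 but -omega/theta is not a positive integer, in which
        case the recurrence does not define a valid pmf (the pgf, p0 and
        moments remain well defined).
        """
        if self.is_poisson or self.theta > 0:
            return None
        n_real = -self.omega / self.theta
        n_int = round(n_real)
        if n_int < 1 or abs(n_real - n_int) > _SUPPORT_INT_RTOL * max(1.0, n_real):
            raise ValueError(
                "for theta < 0 the pmf requires -omega/theta to be a positive "
                f"integer; got -omega/theta = {n_real!r}"
            )
        return int(n_int)


def validate_katz_params(omega: float, theta: float) -> KatzParams:
    """Validate (omega, theta) and return a :class:`KatzParams`.

    Raises
    ------
    ValueError
        If ``omega <= 0`` or ``theta >= 1``.
    """
    return KatzParams(float(omega), float(theta))


def katz_log_pmf(params: KatzParams, k) -> np.ndarray | float:
    """Log pmf at count(s) ``k``, computed by the recurrence in log space.

    For theta < 0 the support is {0, ..., N} with N = -omega/theta, which
    must be a positive integer; counts beyond N get probability zero
    (-inf log probability).
    """
    k_arr = np.asarray(k)
    if np.any(k_arr < 0) or not np.issubdtype(k_arr.dtype, np.integer) and np.any(
        k_arr != np.floor(k_arr)
    ):
        raise ValueError("k must be non-negative integer(s)")
    k_arr = k_arr.astype(np.int64)
    kmax = int(k_arr.max()) if k_arr.size else 0

    support = params.finite_support_size()  # raises for invalid theta<0 case

    # log Pr(0), then accumulate log((omega + theta x)/(1 + x)) for x=0..kmax-1
    logp = np.full(kmax + 1, -np.inf)
    if params.is_poisson:
        logp[0] = -params.omega
    else:
        logp[0] = (params.omega / params.theta) * math.log1p(-params.theta)
    x = np.arange(kmax)
    num = params.omega + params.theta * x
    if support is not None:
        num[x >= support] = 0.0  # exact zero beyond the finite support
    with np.errstate(divide="ignore"):
        steps = np.log(num) - np.log1p(x)
    logp[1:] = logp[0] + np.cumsum(steps)
    out = logp[k_arr]
    return out if out.shape else float(out)


def katz_pmf(params: KatzParams, k) -> np.ndarray | float:
    """Probability mass function at count(s) ``k``."""
    return np.exp(katz_log_pmf(params, k))


def katz_p0(params: KatzParams) -> float:
    """Zero-count (cure) probability; defined for every valid (omega, theta)."""
    return params.p0


def katz_pgf(params: KatzParams, s) -> np.ndarray | float:
    """Probability generating function g(s) = E[s^K] for |s| <= 1.

    g(s) = [(1 - theta*s)/(1 - theta)]^(-omega/theta) for theta != 0 and
    exp(-omega*(1 - s)) in the Poisson limit.  g(0) = p0 and g(1) = 1.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(np.abs(s_arr) > 1.0 + 1e-15):
        raise ValueError("pgf argument must satisfy |s| <= 1")
    if params.is_poisson:
        out = np.exp(-params.omega * (1.0 - s_arr))
    else:
        ratio = (1.0 - params.theta * s_arr) / (1.0 - params.theta)
        expo = -params.omega / params.theta
        if np.any(ratio < 0):
            # only meaningful for an integer Binomial exponent N = -omega/theta
            n = params.finite_support_size()
            out = np.sign(ratio) ** n * np.abs(ratio) ** n
        else:
            out = ratio**expo
    return out if out.shape else float(out)


def katz_moments(params: KatzParams) -> tuple[float, float]:
    """Return (mean, dispersion index) = (omega/(1-theta), 1/(1-theta))."""
    return params.mean, params.dispersion_index
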