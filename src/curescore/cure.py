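"""Improper (cure-rate) survival functions built on the Katz clonogen model.

A patient carries a latent number K of clonogens surviving primary
treatment; each clonogen independently produces a detectable recurrence
after a time with survival function A0(t).  The marginal survival of the
time to first recurrence is the probability generating function of K
evaluated at A0(t).  With a Poisson count (the benchmark, group 0) this is

    S0(t) = exp(-omega0 * (1 - A0(t)))

and with a Katz(omega1, theta) count and a log-linear latent shift
A1(t) = A0(t)^(e^alpha) (group 1)

    S1(t) = [(1 - theta * A1(t)) / (1 - theta)]^(-omega1/theta)

(theta -> 0 limit exp(-omega1 * (1 - A1(t)))).  Both are improper: they
plateau at the cure fraction, exp(-omega0) resp. (1-theta)^(omega1/theta),
the probability of zero surviving clonogens.

The log hazard ratio implied by the model is

    upsilon(t) = gamma + alpha + (e^alpha - 1) log A0(t)
                 - log(1 - theta * A0(t)^(e^alpha))

with gamma = log(omega1/omega0); the null hypothesis of no survival
difference is theta = alpha = gamma = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .katz import THETA_ZERO_TOL

__all__ = [
    "CURED",
    "LatentSurvival",
    "UnitExponential",
    "CureModelSpec",
    "solve_omega1_equal_cure",
    "survival_group0",
    "survival_group1",
    "log_hazard_ratio_upsilon",
    "inverse_survival",
]

#: Sentinel event time for cured subjects (no event, ever).
CURED = math.inf


class LatentSurvival:
    """Base class for the per-clonogen (latent) survival function A0.

    Subclasses implement ``survival`` (A0), its inverse, and the density
    D0 = -dA0/dt.  A0 is strictly decreasing with A0(0) = 1, A0(inf) = 0.
    """

    def survival(self, t):
        raise NotImplementedError

    def inverse(self, a):
        """Time t with A0(t) = a, for a in (0, 1]."""
        raise NotImplementedError

    def density(self, t):
        raise NotImplementedError

    def shifted_survival(self, t, alpha: float):
        """Log-linear shift A0(t, alpha) = A0(t)^(e^alpha); A0(t, 0) = A0(t)."""
        return np.asarray(self.survival(t)) ** math.exp(alpha)


class UnitExponential(LatentSurvival):
    """Unit-exponential latent survival A0(t) = exp(-t), the default baseline."""

    def survival(self, t):
        return np.exp(-np.asarray(t, dtype=float))

    def inverse(self, a):
        a = np.asarray(a, dtype=float)
        if np.any(a <= 0) or np.any(a > 1):
            raise ValueError("inverse argument must lie in (0, 1]")
        return -np.log(a)

    def density(self, t):
        return np.exp(-np.asarray(t, dtype=float))


def solve_omega1_equal_cure(theta: float, omega0: float) -> float:
    """Mean clonogen count omega1 giving group 1 the same cure fraction as group 0.

    Solves (1 - theta)^(omega1/theta) = exp(-omega0), i.e.
    omega1 = -omega0 * theta / log(1 - theta); returns omega0 at theta = 0.
    """
    if omega0 <= 0:
        raise ValueError("omega0 must be positive")
    if theta >= 1:
        raise ValueError("theta must be < 1")
    if abs(theta) < THETA_ZERO_TOL:
        return float(omega0)
    return -omega0 * theta / math.log1p(-theta)


@dataclass(frozen=True)
class CureModelSpec:
    """Fully specified two-group Katz cure model.

    Parameters
    ----------
    omega0 : float
        Mean clonogen count in group 0 (the Poisson parameter); the group-0
        cure fraction is exp(-omega0).
    theta : float
        Katz dispersion parameter of the group-1 count (< 1); 0 recovers
        the Poisson benchmark.
    alpha : float
        Latent-survival shift: group 1 uses A1(t) = A0(t)^(e^alpha).
        alpha > 0 means earlier relapses in group 1.
    omega1 : float, optional
        Mean clonogen count in group 1.  If omitted it is derived as
        e^gamma times the equal-cure-fraction value (gamma defaulting to 0).
    gamma : float
        Recorded log cure-burden shift, log(omega1/omega0) in the Poisson
        benchmark parameterization; acts multiplicatively on the
        equal-cure omega1 when omega1 is derived.
    latent : LatentSurvival
        Baseline per-clonogen survival A0; unit exponential by default.
    """

    omega0: float
    theta: float = 0.0
    alpha: float = 0.0
    gamma: float = 0.0
    omega1: float | None = None
    latent: LatentSurvival = field(default_factory=UnitExponential)

    def __post_init__(self) -> None:
        if self.omega0 <= 0:
            raise ValueError("omega0 must be positive")
        if self.theta >= 1:
            raise ValueError("theta must be < 1")
        if self.omega1 is None:
            w1 = math.exp(self.gamma) * solve_omega1_equal_cure(self.theta, self.omega0)
            object.__setattr__(self, "omega1", w1)
        elif self.omega1 <= 0:
            raise ValueError("omega1 must be positive")

    @property
    def theta_is_zero(self) -> bool:
        return abs(self.theta) < THETA_ZERO_TOL

    @property
    def cure_fraction0(self) -> float:
        return math.exp(-self.omega0)

    @property
    def cure_fraction1(self) -> float:
        if self.theta_is_zero:
            return math.exp(-self.omega1)
        return math.exp((self.omega1 / self.theta) * math.log1p(-self.theta))

    def cure_fraction(self, group: int) -> float:
        return self.cure_fraction0 if group == 0 else self.cure_fraction1

    def survival(self, group: int, t):
        if group == 0:
            return survival_group0(self, t)
        if group == 1:
            return survival_group1(self, t)
        raise ValueError("group must be 0 or 1")

    def plot_survival(self, t_max: float = 8.0, n_points: int = 400, ax=None):
        """Plot the two marginal survival curves (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.linspace(0.0, t_max, n_points)
        ax.plot(t, survival_group0(self, t), color="black", label="group 0")
        ax.plot(t, survival_group1(self, t), color="tab:red", label="group 1")
        ax.set_xlabel("time")
        ax.set_ylabel("marginal survival")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax


def survival_group0(spec: CureModelSpec, t):
    """Group-0 marginal survival S0(t) = exp(-omega0 * (1 - A0(t)))."""
    a = np.asarray(spec.latent.survival(t), dtype=float)
    out = np.exp(-spec.omega0 * (1.0 - a))
    return out if out.shape else float(out)


def survival_group1(spec: CureModelSpec, t):
    """Group-1 marginal survival under the Katz count with latent shift alpha."""
    a1 = np.asarray(spec.latent.shifted_survival(t, spec.alpha), dtype=float)
    if spec.theta_is_zero:
        out = np.exp(-spec.omega1 * (1.0 - a1))
    else:
        ratio = (1.0 - spec.theta * a1) / (1.0 - spec.theta)
        out = ratio ** (-spec.omega1 / spec.theta)
    return out if out.shape else float(out)


def log_hazard_ratio_upsilon(spec: CureModelSpec, t):
    """Log hazard ratio upsilon(t) = log(lambda1(t)/lambda0(t)) under the model.

    upsilon(t) = gamma + alpha + (e^alpha - 1) * log A0(t)
                 - log(1 - theta * A0(t)^(e^alpha)),

    identically zero at the null gamma = theta = alpha = 0.
    """
    a0 = np.asarray(spec.latent.survival(t), dtype=float)
    if np.any(a0 <= 0) or np.any(a0 > 1):
        raise ValueError("A0(t) must lie in (0, 1]")
    ea = math.exp(spec.alpha)
    inner = spec.theta * a0**ea
    if np.any(inner >= 1):
        raise ValueError("theta * A0(t)^(e^alpha) must stay below 1")
    gamma = math.log(spec.omega1 / spec.omega0)
    out = gamma + spec.alpha + (ea - 1.0) * np.log(a0) - np.log1p(-inner)
    return out if out.shape else float(out)


def inverse_survival(spec: CureModelSpec, group: int, u):
    """Invert the marginal survival: the time t with S_group(t) = u.

    Values of u at or below the group's cure fraction map to the CURED
    sentinel (infinite time: the event never occurs).  u must lie in (0, 1].
    """
    u_arr = np.asarray(u, dtype=float)
    scalar = u_arr.ndim == 0
    u_arr = np.atleast_1d(u_arr)
    if np.any(u_arr <= 0) or np.any(u_arr > 1):
        raise ValueError("u must lie in (0, 1]")

    pi = spec.cure_fraction(group)
    out = np.full(u_arr.shape, CURED)
    alive = u_arr > pi
    ua = u_arr[alive]
    if group == 0:
        # S0 = exp(-omega0 (1 - a))  =>  a = 1 + log(u)/omega0
        a0 = 1.0 + np.log(ua) / spec.omega0
    else:
        if spec.theta_is_zero:
            a1 = 1.0 + np.log(ua) / spec.omega1
        else:
            # [(1 - theta a1)/(1 - theta)]^(-omega1/theta) = u
            a1 = (1.0 - (1.0 - spec.theta) * ua ** (-spec.theta / spec.omega1)) / spec.theta
        a0 = a1 ** math.exp(-spec.alpha)
    a0 = np.clip(a0, np.finfo(float).tiny, 1.0)
    out[alive] = spec.latent.inverse(a0)
    return float(out[0]) if scalar else out
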