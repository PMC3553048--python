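"""Three-degree-of-freedom score test for complex two-group survival differences.

The test targets the null hypothesis theta = alpha = gamma = 0 of the Katz
cure model: no difference between groups in dispersion of the clonogen
count, latent progression dynamics, or cure burden.  Its score vector is a
triple of weighted logrank-type sums over event times t_j,

    V_r = sum_j  delta_j * w_r(t_j) * (G_j - S1(t_j)/S0(t_j)),

with weights

    w_alpha(t) = 1 + log(1 - NA(t-)/omega0_hat)
    w_theta(t) = 1 - NA(t-)/omega0_hat
    w_gamma(t) = 1,

where NA(t-) is the left-continuous pooled Nelson-Aalen estimate and
omega0_hat its total value at the last failure time.  Under the null
Poisson model w_theta estimates the latent survival A0(t).  The observed
information is

    I_rs = sum_j delta_j * w_r(t_j) * w_s(t_j) * v_j,
    v_j = S2/S0 - (S1/S0)^2  (the risk-set variance of G),

and S_H0 = V' I^{-1} V is asymptotically chi-square with 3 df.  The
gamma-direction alone reproduces the classical logrank test, which is
exposed as the comparator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hazard import SurvivalDataset, StepHazardEstimate, nelson_aalen

__all__ = [
    "DegenerateDesignError",
    "ScoreTestResult",
    "LogrankResult",
    "CureScoreModel",
    "CureScoreResults",
    "score_weights",
    "score_vector",
    "information_matrix",
    "score_statistic",
    "logrank_test",
]

_PARAM_NAMES = ("alpha", "theta", "gamma")
_MAX_CONDITION = 1e12


class DegenerateDesignError(ValueError):
    """Raised when the information matrix is singular or near-singular.

    Typical causes: fewer than three distinct event times, all events at a
    single time, or one group contributing no events at all.
    """


@dataclass(frozen=True)
class ScoreTestResult:
    """Score vector, information matrix, statistic and chi2(3) p-value."""

    score: np.ndarray
    information: np.ndarray
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class LogrankResult:
    """Classical two-sample logrank test: chi2(1) statistic and p-value."""

    statistic: float
    df: int
    p_value: float


def _event_table(data: SurvivalDataset):
    """Aggregate the sample into distinct event times.

    Returns (times, d, d1, at_risk, at_risk1): events and group-1 events at
    each distinct failure time, with pooled and group-1 risk-set counts.
    """
    t_sorted = np.sort(data.time)
    t1_sorted = np.sort(data.time[data.group == 1])
    ev = data.event == 1
    uniq, inv, d = np.unique(data.time[ev], return_inverse=True, return_counts=True)
    d1 = np.bincount(inv, weights=data.group[ev].astype(float), minlength=len(uniq))
    at_risk = len(data) - np.searchsorted(t_sorted, uniq, side="left")
    at_risk1 = len(t1_sorted) - np.searchsorted(t1_sorted, uniq, side="left")
    return uniq, d.astype(float), d1, at_risk.astype(float), at_risk1.astype(float)


def _check_two_groups(data: SurvivalDataset) -> None:
    n0, n1 = data.group_sizes
    if n0 == 0 or n1 == 0:
        raise ValueError("both groups must be present in the sample")
    if data.n_events == 0:
        raise ValueError("at least one event is required")


def score_weights(est: StepHazardEstimate, t_j) -> tuple:
    """Score weights (a, b, c) at an event time t_j.

    a = 1 + log(1 - NA(t_j-)/omega0_hat), b = 1 - NA(t_j-)/omega0_hat,
    c = 1.  Requires NA(t_j-) < omega0_hat, which holds whenever the
    plug-in omega0_hat includes the final jump.
    """
    ratio = np.asarray(est.cumhaz_left(t_j)) / est.omega0_hat
    if np.any(ratio >= 1.0):
        raise ValueError(
            "left-continuous cumulative hazard reached omega0_hat; "
            "the log weight is undefined"
        )
    b = 1.0 - ratio
    a = 1.0 + np.log(b)
    c = np.ones_like(b)
    if b.shape:
        return a, b, c
    return float(a), float(b), float(c)


def _weights_and_variance(data: SurvivalDataset):
    """Per-distinct-event-time weights, risk-set means and variances."""
    est = nelson_aalen(data)
    times, d, d1, at_risk, at_risk1 = _event_table(data)
    # NA(t-) via exclusive cumulative sum of the jumps
    cum = np.cumsum(d / at_risk)
    cum_left = np.concatenate(([0.0], cum[:-1]))
    w_hat = est.omega0_hat
    b = 1.0 - cum_left / w_hat
    a = 1.0 + np.log(b)
    w = np.vstack([a, b, np.ones_like(b)])  # rows: alpha, theta, gamma
    e_bar = at_risk1 / at_risk  # S1/S0 at each event time
    v = e_bar * (1.0 - e_bar)  # S2/S0 - (S1/S0)^2, G binary
    return w, d, d1, e_bar, v


def score_vector(data: SurvivalDataset) -> np.ndarray:
    """Score 3-vector (V_alpha, V_theta, V_gamma) evaluated at the null."""
    _check_two_groups(data)
    w, d, d1, e_bar, _ = _weights_and_variance(data)
    resid = d1 - d * e_bar  # observed minus expected group-1 events
    return w @ resid


def information_matrix(data: SurvivalDataset) -> np.ndarray:
    """Observed 3x3 information of (alpha, theta, gamma) at the null."""
    _check_two_groups(data)
    w, d, _, _, v = _weights_and_variance(data)
    return (w * (d * v)) @ w.T


def score_statistic(data: SurvivalDataset) -> ScoreTestResult:
    """The 3-df score statistic S_H0 = V' I^{-1} V with chi2(3) p-value.

    Raises
    ------
    DegenerateDesignError
        If the information matrix is singular or its condition number
        exceeds 1e12 (degenerate design, e.g. < 3 distinct event times).
    """
    _check_two_groups(data)
    w, d, d1, e_bar, v = _weights_and_variance(data)
    V = w @ (d1 - d * e_bar)
    I = (w * (d * v)) @ w.T
    cond = np.linalg.cond(I)
    if not np.isfinite(cond) or cond > _MAX_CONDITION:
        raise DegenerateDesignError(
            f"information matrix is numerically singular (condition number {cond:.3g}); "
            "the design is degenerate — need at least 3 distinct event times with "
            "both groups at risk"
        )
    stat = float(V @ np.linalg.solve(I, V))
    stat = max(stat, 0.0)
    return ScoreTestResult(
        score=V,
        information=I,
        statistic=stat,
        df=3,
        p_value=float(stats.chi2.sf(stat, 3)),
    )


def logrank_test(data: SurvivalDataset) -> LogrankResult:
    """Classical two-sample logrank test, V_gamma^2 / I_gammagamma ~ chi2(1)."""
    _check_two_groups(data)
    _, d, d1, e_bar, v = _weights_and_variance(data)
    num = float(np.sum(d1 - d * e_bar))
    var = float(np.sum(d * v))
    if var <= 0:
        raise ValueError("logrank variance is zero; groups are not comparable")
    stat = num * num / var
    return LogrankResult(statistic=stat, df=1, p_value=float(stats.chi2.sf(stat, 1)))


class CureScoreModel:
    """Two-group survival comparison under the Katz cure model.

    The "fit" evaluates the 3-df score test of the null hypothesis of no
    survival difference (theta = alpha = gamma = 0), together with the
    classical logrank comparator, using the pooled Nelson-Aalen plug-in
    estimates; no parameters are estimated under the alternative.

    Parameters
    ----------
    durations : array-like
        Observed follow-up times, non-negative.
    event_observed : array-like
        Binary event indicators (1 = event, 0 = censored).
    groups : array-like
        Binary group labels.

    Examples
    --------
    >>> model = CureScoreModel(durations, event_observed=status, groups=g)
    >>> res = model.fit()
    >>> res.statistic, res.p_value  # doctest: +SKIP
    """

    def __init__(self, durations, event_observed, groups):
        self.data = SurvivalDataset(
            np.asarray(durations, dtype=float),
            np.asarray(event_observed),
            np.asarray(groups),
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time_col: str = "time",
        event_col: str = "status",
        group_col: str = "group",
    ) -> "CureScoreModel":
        ds = SurvivalDataset.from_dataframe(df, time_col, event_col, group_col)
        return cls(ds.time, ds.event, ds.group)

    def fit(self) -> "CureScoreResults":
        est = nelson_aalen(self.data)
        score = score_statistic(self.data)
        lr = logrank_test(self.data)
        return CureScoreResults(self, est, score, lr)


class CureScoreResults:
    """Results of a fitted :class:`CureScoreModel`.

    Attributes
    ----------
    statistic, df, p_value : the 3-df score test.
    score : pd.Series of (V_alpha, V_theta, V_gamma).
    information : pd.DataFrame, observed 3x3 information.
    logrank : LogrankResult, the classical comparator.
    omega0_hat : plug-in mean clonogen count (total cumulative hazard).
    """

    def __init__(self, model, hazard_estimate, score_result, logrank_result):
        self.model = model
        self.hazard_estimate = hazard_estimate
        self._score = score_result
        self.logrank = logrank_result

    @property
    def score(self) -> pd.Series:
        return pd.Series(self._score.score, index=list(_PARAM_NAMES), name="score")

    @property
    def information(self) -> pd.DataFrame:
        return pd.DataFrame(
            self._score.information, index=list(_PARAM_NAMES), columns=list(_PARAM_NAMES)
        )

    @property
    def statistic(self) -> float:
        return self._score.statistic

    @property
    def df(self) -> int:
        return self._score.df

    @property
    def p_value(self) -> float:
        return self._score.p_value

    @property
    def omega0_hat(self) -> float:
        return self.hazard_estimate.omega0_hat

    def to_dict(self) -> dict:
        """Machine-readable summary of both tests."""
        n0, n1 = self.model.data.group_sizes
        return {
            "n": len(self.model.data),
            "n_group0": n0,
            "n_group1": n1,
            "n_events": self.model.data.n_events,
            "omega0_hat": self.omega0_hat,
            "score_test": {
                "statistic": self.statistic,
                "df": self.df,
                "p_value": self.p_value,
                "score_vector": self._score.score.tolist(),
            },
            "logrank": {
                "statistic": self.logrank.statistic,
                "df": self.logrank.df,
                "p_value": self.logrank.p_value,
            },
        }

    def summary(self) -> str:
        """Plain-text summary table of the score test and logrank comparator."""
        n0, n1 = self.model.data.group_sizes
        lines = [
            "Katz cure-model score test (H0: theta = alpha = gamma = 0)",
            "=" * 62,
            f"subjects: {len(self.model.data)}  (group 0: {n0}, group 1: {n1})"
            f"   events: {self.model.data.n_events}",
            f"plug-in omega0_hat (total cumulative hazard): {self.omega0_hat:.4f}",
            "-" * 62,
            f"{'test':<22}{'statistic':>12}{'df':>5}{'p-value':>14}",
            f"{'score (3 df)':<22}{self.statistic:>12.4f}{self.df:>5}{self.p_value:>14.4g}",
            f"{'logrank':<22}{self.logrank.statistic:>12.4f}{self.logrank.df:>5}"
            f"{self.logrank.p_value:>14.4g}",
            "-" * 62,
            "score vector (alpha, theta, gamma): "
            + np.array2string(self._score.score, precision=4),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<CureScoreResults statistic={self.statistic:.4f} "
            f"df={self.df} p={self.p_value:.4g}>"
        )
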