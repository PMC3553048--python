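"""Right-censored two-group survival data and counting-process estimators.

Provides the pooled-sample Nelson-Aalen cumulative-hazard estimator (with
its left-continuous evaluator), the plug-in total hazard omega0_hat =
NA(t_max) used as estimator of the mean clonogen count under the null, and
the risk-set moments S^(r) of the group indicator that enter the score
test's variance terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "StepHazardEstimate",
    "nelson_aalen",
    "omega0_hat",
    "risk_set_moments",
]


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored two-group sample: (time, event, group) per subject.

    time : observed follow-up X = min(T*, C), non-negative (infinite times
    are not allowed: cured subjects must be administratively censored).
    event : 1 if the event was observed at X, 0 if censored.
    group : binary group indicator G.
    """

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        d = np.asarray(self.event)
        g = np.asarray(self.group)
        if not (t.ndim == d.ndim == g.ndim == 1) or not (len(t) == len(d) == len(g)):
            raise ValueError("time, event and group must be 1-d arrays of equal length")
        if len(t) == 0:
            raise ValueError("dataset is empty")
        if np.any(~np.isfinite(t)) or np.any(t < 0):
            raise ValueError("times must be finite and non-negative")
        for name, arr in (("event", d), ("group", g)):
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"{name} indicator must be binary 0/1, got values {vals}")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", d.astype(np.int8))
        object.__setattr__(self, "group", g.astype(np.int8))

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def group_sizes(self) -> tuple[int, int]:
        n1 = int(self.group.sum())
        return len(self) - n1, n1

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time_col: str = "time",
        event_col: str = "status",
        group_col: str = "group",
    ) -> "SurvivalDataset":
        return cls(
            df[time_col].to_numpy(dtype=float),
            df[event_col].to_numpy(),
            df[group_col].to_numpy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "status": self.event, "group": self.group}
        )


@dataclass(frozen=True)
class StepHazardEstimate:
    """Pooled Nelson-Aalen estimate as a step function.

    event_times : ordered distinct failure times t_(1) < ... < t_(m).
    jumps : d_k / Y(t_(k)), events over number at risk, tied events pooled.
    cum_right : right-continuous cumulative values (inclusive of the jump).
    omega0_hat : total cumulative hazard through the last failure time,
        NA(t_max) including its jump, the plug-in estimate of omega0.
    """

    event_times: np.ndarray
    jumps: np.ndarray
    cum_right: np.ndarray

    @property
    def omega0_hat(self) -> float:
        return float(self.cum_right[-1])

    def cumhaz_left(self, t) -> np.ndarray | float:
        """Left-continuous evaluation NA(t-): jumps strictly before t."""
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float), side="left")
        padded = np.concatenate(([0.0], self.cum_right))
        out = padded[idx]
        return out if out.shape else float(out)

    def cumhaz_right(self, t) -> np.ndarray | float:
        """Right-continuous evaluation NA(t): jumps at or before t."""
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float), side="right")
        padded = np.concatenate(([0.0], self.cum_right))
        out = padded[idx]
        return out if out.shape else float(out)


def nelson_aalen(data: SurvivalDataset) -> StepHazardEstimate:
    """Pooled-sample Nelson-Aalen estimator of the cumulative hazard.

    Ties between an event and a censoring at the same time follow the
    standard convention that events happen first, so the censored subject
    still counts in the risk set at that time.

    Raises
    ------
    ValueError
        If the dataset contains no events.
    """
    if data.n_events == 0:
        raise ValueError("cannot estimate a cumulative hazard from a sample with no events")
    t_sorted = np.sort(data.time)
    ev_times = data.time[data.event == 1]
    uniq, counts = np.unique(ev_times, return_counts=True)
    # number at risk Y(t) = #{j : X_j >= t}
    at_risk = len(data) - np.searchsorted(t_sorted, uniq, side="left")
    jumps = counts / at_risk
    return StepHazardEstimate(uniq, jumps, np.cumsum(jumps))


def omega0_hat(est: StepHazardEstimate) -> float:
    """Plug-in omega0: the Nelson-Aalen value at the last observed failure."""
    return est.omega0_hat


def risk_set_moments(data: SurvivalDataset, t) -> tuple:
    """Risk-set moments S^(r)(t) = n^-1 sum_k Y_k(t) G_k^r for r = 0, 1, 2.

    Since G is binary, S^(2) = S^(1) exactly; all three are returned to
    mirror the general weighted-sum notation.
    """
    t_arr = np.asarray(t, dtype=float)
    at_risk = data.time[:, None] >= t_arr.reshape(1, -1) if t_arr.ndim else data.time >= t_arr
    n = len(data)
    if t_arr.ndim:
        s0 = at_risk.sum(axis=0) / n
        s1 = (at_risk * (data.group[:, None] == 1)).sum(axis=0) / n
        return s0, s1, s1.copy()
    s0 = float(np.sum(at_risk)) / n
    s1 = float(np.sum(at_risk & (data.group == 1))) / n
    return s0, s1, s1
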