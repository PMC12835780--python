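"""Breslow baseline-hazard recovery and absolute survival curves.

A trained Cox-type model yields only relative log-hazard scores; converting
them into survival probabilities needs the nonparametric baseline hazard.
At each unique event time t_j with d_j events, the discrete Breslow
increment is

    h0(t_j) = d_j / sum_{l in R(t_j)} exp f(x_l),

with the risk set R(t_j) = {l : o_l >= t_j} (subjects censored exactly at
t_j remain in the risk set). The predicted survival of subject i is then
the right-continuous step function

    S_i(t) = exp( - H0(t) * exp f(x_i) ),   H0(t) = sum_{t_j <= t} h0(t_j).

With constant scores the increments reduce to the Nelson-Aalen estimator
d_j / |R(t_j)|, and adding a constant c to every score rescales the
increments by exp(-c) and the subject multiplier by exp(c), leaving S
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort_io import SurvivalCohort
from .dcph import RiskOutput, _as_scores


@dataclass(frozen=True)
class BaselineHazard:
    """Discrete baseline-hazard increments on the unique event-time grid."""

    event_times: np.ndarray
    increments: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        h = np.asarray(self.increments, dtype=float)
        if t.ndim != 1 or t.shape != h.shape:
            raise ValueError("event_times and increments must be 1-d and aligned")
        if np.any(np.diff(t) <= 0):
            raise ValueError("event_times must be strictly increasing")
        if np.any(h < 0):
            raise ValueError("hazard increments must be nonnegative")
        object.__setattr__(self, "event_times", t)
        object.__setattr__(self, "increments", h)

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.increments)

    def cumulative_at(self, times) -> np.ndarray:
        """H0(t) evaluated at arbitrary times (0 before the first event)."""
        t = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        cum = np.concatenate([[0.0], self.cumulative])
        return cum[idx]


@dataclass(frozen=True)
class SurvivalCurve:
    """Per-subject survival probabilities on a shared evaluation grid."""

    times: np.ndarray
    probabilities: np.ndarray  # (n_subjects, n_times)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.atleast_2d(np.asarray(self.probabilities, dtype=float))
        if p.shape[1] != t.shape[0]:
            raise ValueError("probabilities must have one column per time")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if t.size > 1 and np.any(np.diff(p, axis=1) > 1e-12):
            raise ValueError("survival probabilities must be non-increasing in t")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "probabilities", np.clip(p, 0.0, 1.0))


def breslow_fit(scores, cohort: SurvivalCohort) -> BaselineHazard:
    """Estimate the discrete baseline hazard from scores and observed data."""
    s = _as_scores(scores)
    if cohort.n_events == 0:
        raise ValueError("cannot fit a baseline hazard without events")
    shift = s.max()
    es = np.exp(s - shift)  # stabilized; undone below
    order = np.argsort(cohort.time, kind="stable")
    t = cohort.time[order]
    ev = cohort.event[order]
    w = es[order]
    # total risk mass with o_l >= t, computed as a reverse cumulative sum
    suffix = np.cumsum(w[::-1])[::-1]
    new_block = np.empty(t.shape[0], dtype=bool)
    new_block[0] = True
    new_block[1:] = t[1:] > t[:-1]
    block_start = np.flatnonzero(new_block)
    block_id = np.cumsum(new_block) - 1
    risk_mass = suffix[block_start]  # per unique time
    d = np.bincount(block_id, weights=ev)
    event_block = d > 0
    if not np.all(risk_mass[event_block] > 0):
        raise AssertionError("empty risk set at an event time")
    times_u = t[block_start]
    increments = d[event_block] / risk_mass[event_block] * np.exp(-shift)
    return BaselineHazard(event_times=times_u[event_block], increments=increments)


def predict_survival(scores, hazard: BaselineHazard, times) -> SurvivalCurve:
    """S_i(t) = exp(-H0(t) exp(f(x_i))) on the requested grid."""
    s = _as_scores(scores)
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("evaluation times must be nonnegative")
    H = hazard.cumulative_at(t)  # (n_times,)
    probs = np.exp(-np.outer(np.exp(s), H))
    return SurvivalCurve(times=t, probabilities=probs)
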