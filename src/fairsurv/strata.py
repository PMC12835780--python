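"""Risk stratification and survival-curve audits across sensitive groups.

Subjects are binned into low / mid / high predicted-risk categories by score
quantiles (default: bottom 25%, middle 50%, top 25%). Within each stratum
the observed survival of every sensitive group is estimated with
Kaplan-Meier, and all group pairs are compared with two-sided log-rank
tests. Under a fair model the observed survival curves inside one predicted
risk category should not differ systematically by group: a group whose
observed survival sits significantly below the others in the high-risk
stratum is having its risk underestimated.

Kaplan-Meier estimation and the log-rank test are delegated to lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .cohort_io import SurvivalCohort
from .dcph import _as_scores

logger = logging.getLogger("fairsurv")

STRATA = ("low", "mid", "high")


def stratify(scores, cutpoints: tuple[float, float] = (0.25, 0.75)) -> np.ndarray:
    """Assign 'low'/'mid'/'high' labels by score quantiles.

    ``low``: score strictly below the q_low quantile; ``high``: strictly
    above the q_high quantile; everything else (including all boundary ties)
    is ``mid``. With all scores identical every subject is mid, with a
    warning. Higher score always means higher predicted risk.
    """
    s = _as_scores(scores)
    q_low, q_high = cutpoints
    if not 0.0 < q_low < q_high < 1.0:
        raise ValueError("cutpoints must satisfy 0 < q_low < q_high < 1")
    if s.size < 3:
        raise ValueError("need at least as many subjects as strata")
    t_low, t_high = np.quantile(s, [q_low, q_high])
    labels = np.full(s.size, "mid", dtype=object)
    labels[s < t_low] = "low"
    labels[s > t_high] = "high"
    if np.ptp(s) == 0:
        logger.warning("stratify: all scores identical; every subject is mid risk")
    return labels


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate with at-risk counts at event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def at(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        out = np.ones(np.asarray(t, dtype=float).shape)
        pos = idx >= 0
        out[pos] = self.survival[idx[pos]]
        return out


def kaplan_meier(times, events) -> KMCurve:
    """Kaplan-Meier estimate of the survival function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = np.array([(times >= t).sum() for t in grid])
    return KMCurve(times=grid, survival=surv, at_risk=at_risk)


def logrank_test(times, events, groups, pair: tuple[int, int]):
    """Two-sample two-sided log-rank test between two group labels.

    Returns ``(statistic, p_value)`` or ``(None, None)`` (defined-missing)
    when the two samples have no events at all.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    groups = np.asarray(groups)
    a, b = pair
    ma, mb = groups == a, groups == b
    if not (ma.any() and mb.any()):
        raise ValueError(f"both groups of pair {pair} must be non-empty")
    if events[ma | mb].sum() == 0:
        return None, None
    res = _ll_logrank(times[ma], times[mb], event_observed_A=events[ma],
                      event_observed_B=events[mb])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class StratificationResult:
    """Risk categories, per-stratum per-group KM curves, pairwise tests."""

    stratum: np.ndarray                      # per-subject label in STRATA
    km_curves: dict                          # (stratum, group name) -> KMCurve
    tests: dict                              # (stratum, name_a, name_b) -> (stat, p)
    verdicts: dict                           # stratum -> verdict string
    alpha: float
    bonferroni: bool

    def to_dict(self) -> dict:
        return {
            "strata_sizes": {s: int((self.stratum == s).sum()) for s in STRATA},
            "tests": {
                f"{s}|{a}|{b}": {"statistic": st, "p_value": p}
                for (s, a, b), (st, p) in self.tests.items()
            },
            "verdicts": self.verdicts,
            "alpha": self.alpha,
            "bonferroni": self.bonferroni,
        }


def audit(
    model,
    cohort: SurvivalCohort,
    cutpoints: tuple[float, float] = (0.25, 0.75),
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> StratificationResult:
    """Stratify by predicted risk and log-rank test every group pair per stratum.

    ``model`` is a FittedModel or precomputed scores. The verdict per stratum
    names the significant pairs at level ``alpha`` (optionally Bonferroni-
    adjusted over the pairs within the stratum), or states that none differ.
    """
    scores = model.predict(cohort).scores if hasattr(model, "predict") else _as_scores(model)
    labels = stratify(scores, cutpoints)
    km_curves: dict = {}
    tests: dict = {}
    verdicts: dict = {}
    for s in STRATA:
        in_s = labels == s
        present = [g for g in range(1, cohort.n_groups + 1)
                   if np.any(in_s & (cohort.group == g))]
        for g in present:
            name = cohort.group_names[g - 1]
            m = in_s & (cohort.group == g)
            km_curves[(s, name)] = kaplan_meier(cohort.time[m], cohort.event[m])
        if len(present) < 2:
            verdicts[s] = "fewer than 2 groups represented; no comparisons"
            continue
        n_pairs = len(present) * (len(present) - 1) // 2
        level = alpha / n_pairs if bonferroni else alpha
        significant = []
        for a, b in combinations(present, 2):
            na, nb = cohort.group_names[a - 1], cohort.group_names[b - 1]
            stat, p = logrank_test(cohort.time[in_s], cohort.event[in_s],
                                   cohort.group[in_s], (a, b))
            tests[(s, na, nb)] = (stat, p)
            if p is not None and p < level:
                significant.append(f"{na} vs {nb}")
        if significant:
            verdicts[s] = ("significant pairwise differences at alpha="
                           f"{alpha}{' (Bonferroni)' if bonferroni else ''}: "
                           + "; ".join(significant))
        else:
            verdicts[s] = f"no significant pairwise difference at alpha={alpha}"
    return StratificationResult(
        stratum=labels, km_curves=km_curves, tests=tests,
        verdicts=verdicts, alpha=alpha, bonferroni=bonferroni,
    )
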