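"""Discrimination and calibration metrics, overall and per group.

Discrimination is measured with Harrell's concordance index over comparable
pairs (i, j): o_i < o_j and the earlier subject's event observed. Three pair
sets are supported for a sensitive group k:

* ``all`` — every comparable pair (overall Harrell's C);
* ``within`` k — both members in group k (intra-group ranking only);
* ``cross`` k — exactly one member in group k: does the model rank group-k
  subjects correctly *against the rest of the cohort*? This is the fairness
  lens: a model can rank well inside every group yet systematically mis-rank
  one group against the others.

Every cross pair belongs to exactly two groups' cross sets, so the pair
counts satisfy |all| = sum_k |within_k| + (1/2) sum_k |cross_k|.

Calibration uses the inverse-probability-of-censoring-weighted (IPCW)
integrated Brier score and the integrated calibration index (ICI): the
time-averaged mean absolute gap between predicted survival probabilities
and a loess-type calibration curve of observed status on predicted
probability. The censoring distribution G is a Kaplan-Meier fit on the full
cohort with censoring as the event.

Confidence intervals come from a subject-level percentile bootstrap; all
metrics are recomputed on each resample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from numba import njit

from .cohort_io import SurvivalCohort
from .breslow import SurvivalCurve
from .dcph import _as_scores

logger = logging.getLogger("fairsurv")


# ---------------------------------------------------------------------------
# Comparable pairs (explicit, for small cohorts and the type contract)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparablePairSet:
    """Explicit ordered pairs (i, j): o_i < o_j and subject i's event observed."""

    pairs: tuple[tuple[int, int], ...]
    variant: str  # "all", "within:k", "cross:k"

    @classmethod
    def build(cls, cohort: SurvivalCohort, variant="all") -> "ComparablePairSet":
        kind, k = _parse_variant(cohort, variant)
        pairs = []
        for i in range(cohort.n):
            if cohort.event[i] != 1:
                continue
            for j in range(cohort.n):
                if cohort.time[i] >= cohort.time[j]:
                    continue
                gi, gj = cohort.group[i], cohort.group[j]
                if kind == "within" and not (gi == k and gj == k):
                    continue
                if kind == "cross" and not ((gi == k) ^ (gj == k)):
                    continue
                pairs.append((i, j))
        name = kind if kind == "all" else f"{kind}:{k}"
        return cls(pairs=tuple(pairs), variant=name)


def _parse_variant(cohort: SurvivalCohort, variant):
    """Normalize a variant spec to ("all"|"within"|"cross", group_code)."""
    if variant == "all" or variant is None:
        return "all", 0
    kind, k = variant
    if kind not in ("within", "cross"):
        raise ValueError(f"unknown pair-set variant {variant!r}")
    if isinstance(k, str):
        k = cohort.group_names.index(k) + 1
    if not 1 <= k <= cohort.n_groups:
        raise ValueError(f"group {k} out of range")
    return kind, int(k)


# ---------------------------------------------------------------------------
# Fast pair counting: one pass over all variants (Fenwick trees per group)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _pair_count_kernel(t, delta, grp, rank, K, R):  # pragma: no cover (jit)
    # Fenwick trees over score ranks, one per group; subjects are inserted in
    # decreasing time order so the trees always hold {j : o_j > o_i}.
    bit = np.zeros((K + 1, R + 1))
    active = np.zeros(K + 1)
    conc = np.zeros((3, K + 1))  # rows: concordant, tied, total
    w_conc = np.zeros((3, K + 1))
    x_conc = np.zeros((3, K + 1))
    n = t.shape[0]
    i = n - 1
    while i >= 0:
        j = i
        while j > 0 and t[j - 1] == t[i]:
            j -= 1
        for m in range(j, i + 1):
            if delta[m] == 1:
                gi = grp[m]
                rm = rank[m]
                for g in range(1, K + 1):
                    # count active group-g subjects with lower / equal rank
                    lt = 0.0
                    r = rm - 1
                    while r > 0:
                        lt += bit[g, r]
                        r -= r & (-r)
                    le = 0.0
                    r = rm
                    while r > 0:
                        le += bit[g, r]
                        r -= r & (-r)
                    eq = le - lt
                    tot = active[g]
                    conc[0, 0] += lt
                    conc[1, 0] += eq
                    conc[2, 0] += tot
                    if g == gi:
                        w_conc[0, g] += lt
                        w_conc[1, g] += eq
                        w_conc[2, g] += tot
                    else:
                        x_conc[0, gi] += lt
                        x_conc[1, gi] += eq
                        x_conc[2, gi] += tot
                        x_conc[0, g] += lt
                        x_conc[1, g] += eq
                        x_conc[2, g] += tot
        for m in range(j, i + 1):
            g = grp[m]
            active[g] += 1.0
            r = rank[m]
            while r <= R:
                bit[g, r] += 1.0
                r += r & (-r)
        i = j - 1
    return conc, w_conc, x_conc


@dataclass(frozen=True)
class PairCounts:
    """Concordant / tied / total pair counts for every variant at once."""

    all_counts: tuple[float, float, float]
    within: dict = field(default_factory=dict)   # group code -> (conc, tied, total)
    cross: dict = field(default_factory=dict)


def pair_counts(scores, cohort: SurvivalCohort) -> PairCounts:
    """Count concordant/tied/total comparable pairs for all variants.

    Concordant means the earlier-event subject has the strictly higher
    predicted risk; score ties count one half.
    """
    s = _as_scores(scores)
    order = np.argsort(cohort.time, kind="stable")
    t = cohort.time[order]
    delta = cohort.event[order].astype(np.int64)
    grp = cohort.group[order].astype(np.int64)
    ranks = (np.unique(s, return_inverse=True)[1] + 1).astype(np.int64)[order]
    K = cohort.n_groups
    R = int(ranks.max())
    conc, w, x = _pair_count_kernel(t, delta, grp, ranks, K, R)
    return PairCounts(
        all_counts=(conc[0, 0], conc[1, 0], conc[2, 0]),
        within={g: (w[0, g], w[1, g], w[2, g]) for g in range(1, K + 1)},
        cross={g: (x[0, g], x[1, g], x[2, g]) for g in range(1, K + 1)},
    )


def concordance(scores, cohort: SurvivalCohort, variant="all") -> float | None:
    """Concordance index for the requested pair-set variant.

    Returns ``None`` (defined-missing) when the pair set is empty, e.g. a
    group with no observed events.
    """
    kind, k = _parse_variant(cohort, variant)
    counts = pair_counts(scores, cohort)
    if kind == "all":
        c, tied, tot = counts.all_counts
    elif kind == "within":
        c, tied, tot = counts.within[k]
    else:
        c, tied, tot = counts.cross[k]
    if tot == 0:
        logger.info("concordance %s: empty pair set, reported missing", variant)
        return None
    return float((c + 0.5 * tied) / tot)


# ---------------------------------------------------------------------------
# Censoring distribution (IPCW weights)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CensoringDistribution:
    """Kaplan-Meier estimate of the censoring survival G(t), full cohort."""

    times: np.ndarray
    values: np.ndarray

    @classmethod
    def fit(cls, cohort: SurvivalCohort) -> "CensoringDistribution":
        kmf = KaplanMeierFitter()
        kmf.fit(cohort.time, event_observed=1 - cohort.event)
        sf = kmf.survival_function_
        return cls(times=sf.index.to_numpy(dtype=float),
                   values=sf.iloc[:, 0].to_numpy(dtype=float))

    def at(self, t) -> np.ndarray:
        """Right-continuous G(t)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        return self.values[np.maximum(idx, 0)]

    def at_minus(self, t) -> np.ndarray:
        """Left limit G(t-)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="left") - 1
        out = np.ones(np.asarray(t, dtype=float).shape)
        pos = idx >= 0
        out[pos] = self.values[idx[pos]]
        return out


def default_tau(cohort: SurvivalCohort, q: float = 0.99) -> float:
    """Default evaluation horizon: the 99th percentile of follow-up times."""
    return float(np.quantile(cohort.time, q))


def _curve_at(curves: SurvivalCurve, t: float) -> np.ndarray:
    """Step-function lookup of S_i(t) (S=1 before the first grid time)."""
    idx = int(np.searchsorted(curves.times, t, side="right")) - 1
    if idx < 0:
        return np.ones(curves.probabilities.shape[0])
    return curves.probabilities[:, idx]


def ipcw_weights(
    cohort: SurvivalCohort, censoring: CensoringDistribution, t: float
) -> tuple[np.ndarray, int]:
    """IPCW weights w_i(t); returns (weights, n_dropped_for_zero_G).

    w_i(t) = d_i 1(o_i <= t) / G(o_i-) + 1(o_i > t) / G(t). Subjects censored
    before t carry weight zero; terms whose required G value is zero are
    dropped (weight zero) and counted.
    """
    w = np.zeros(cohort.n)
    dropped = 0
    past_event = (cohort.event == 1) & (cohort.time <= t)
    g_minus = censoring.at_minus(cohort.time[past_event])
    ok = g_minus > 0
    idx = np.flatnonzero(past_event)
    w[idx[ok]] = 1.0 / g_minus[ok]
    dropped += int((~ok).sum())
    alive = cohort.time > t
    g_t = float(censoring.at(t))
    if g_t > 0:
        w[alive] = 1.0 / g_t
    else:
        dropped += int(alive.sum())
    return w, dropped


def brier_scores(
    curves: SurvivalCurve,
    cohort: SurvivalCohort,
    times: np.ndarray,
    group=None,
    censoring: CensoringDistribution | None = None,
) -> np.ndarray:
    """IPCW Brier score BS(t) at each requested time.

    BS(t) = (1/n_group) sum_i w_i(t) (1(o_i > t) - S_i(t))^2 with the
    censoring distribution fit on the full cohort.
    """
    censoring = censoring or CensoringDistribution.fit(cohort)
    mask = _group_mask(cohort, group)
    n_grp = int(mask.sum())
    if n_grp == 0:
        raise ValueError("no subjects in the requested group")
    out = np.zeros(np.asarray(times, dtype=float).shape)
    dropped_total = 0
    for gi, t in enumerate(np.asarray(times, dtype=float)):
        S = _curve_at(curves, t)[mask]
        w, dropped = ipcw_weights(cohort, censoring, t)
        dropped_total += dropped
        alive = (cohort.time[mask] > t).astype(float)
        out[gi] = float(np.sum(w[mask] * (alive - S) ** 2) / n_grp)
    if dropped_total:
        logger.info("brier_scores: %d term(s) dropped for zero G", dropped_total)
    return out


def integrated_brier(
    curves: SurvivalCurve,
    cohort: SurvivalCohort,
    group=None,
    tau: float | None = None,
    censoring: CensoringDistribution | None = None,
    grid_size: int = 100,
) -> float:
    """IPCW integrated Brier score over (0, tau], trapezoidal in time.

    ``group`` restricts the subject average to one group (label or name);
    the censoring distribution is always fit on the full cohort. The time
    grid is the unique event times up to tau, thinned to at most
    ``grid_size`` quantile points, with 0 and tau as end points.
    """
    tau = default_tau(cohort) if tau is None else float(tau)
    if tau > cohort.time.max() + 1e-12:
        raise ValueError("tau must not exceed the maximum follow-up time")
    censoring = censoring or CensoringDistribution.fit(cohort)
    grid = _event_grid(cohort, tau, grid_size)
    bs = brier_scores(curves, cohort, grid, group, censoring)
    return float(np.trapezoid(bs, grid) / tau)


def _group_mask(cohort: SurvivalCohort, group) -> np.ndarray:
    if group is None:
        return np.ones(cohort.n, dtype=bool)
    if isinstance(group, str):
        group = cohort.group_names.index(group) + 1
    return cohort.group == int(group)


def _event_grid(cohort: SurvivalCohort, tau: float, grid_size: int) -> np.ndarray:
    et = np.unique(cohort.time[(cohort.event == 1) & (cohort.time <= tau)])
    if et.size > grid_size:
        et = np.unique(np.quantile(et, np.linspace(0, 1, grid_size)))
    return np.unique(np.concatenate([[0.0], et, [tau]]))


# ---------------------------------------------------------------------------
# Integrated calibration index
# ---------------------------------------------------------------------------

def _local_linear_smooth(x, y, w, span=0.75, max_points=512):
    """Weighted loess-type (local-linear, tricube) smoother of y on x.

    For large inputs the data are first aggregated into weighted quantile
    bins (at most ``max_points``) to bound the cost; fitted values at the
    original x are obtained by linear interpolation between bin fits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    keep = w > 0
    if keep.sum() < 2 or np.ptp(x[keep]) < 1e-12:
        # degenerate: fall back to the weighted mean (empirical survival)
        logger.info("calibration smoother: degenerate predictions, using weighted mean")
        mean = np.average(y[keep], weights=w[keep]) if keep.any() else np.nan
        return np.full_like(x, mean)
    xs, ys, ws = x[keep], y[keep], w[keep]
    if xs.size > max_points:
        order = np.argsort(xs, kind="stable")
        xs, ys, ws = xs[order], ys[order], ws[order]
        edges = np.linspace(0, xs.size, max_points + 1).astype(int)
        xb = np.array([np.average(xs[a:b], weights=ws[a:b])
                       for a, b in zip(edges[:-1], edges[1:]) if b > a])
        yb = np.array([np.average(ys[a:b], weights=ws[a:b])
                       for a, b in zip(edges[:-1], edges[1:]) if b > a])
        wb = np.array([ws[a:b].sum() for a, b in zip(edges[:-1], edges[1:]) if b > a])
    else:
        order = np.argsort(xs, kind="stable")
        xb, yb, wb = xs[order], ys[order], ws[order]
    m = xb.size
    k = max(2, int(np.ceil(span * m)))
    fit = np.empty(m)
    for i in range(m):
        d = np.abs(xb - xb[i])
        h = np.partition(d, k - 1)[k - 1]
        h = max(h, 1e-12)
        tri = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        ww = tri * wb
        sw = ww.sum()
        xm = np.sum(ww * xb) / sw
        ym = np.sum(ww * yb) / sw
        sxx = np.sum(ww * (xb - xm) ** 2)
        slope = np.sum(ww * (xb - xm) * (yb - ym)) / sxx if sxx > 1e-14 else 0.0
        fit[i] = ym + slope * (xb[i] - xm)
    # enforce a function of x (bin means are sorted in x; interpolate)
    xb_u, idx = np.unique(xb, return_index=True)
    return np.interp(x, xb_u, fit[idx])


def integrated_calibration_index(
    curves: SurvivalCurve,
    cohort: SurvivalCohort,
    group=None,
    tau: float | None = None,
    censoring: CensoringDistribution | None = None,
    span: float = 0.75,
    n_grid: int = 10,
) -> float:
    """Time-averaged mean |predicted - calibrated| survival probability.

    At each grid time t (deciles of event times up to tau, plus 0 and tau)
    the calibration curve is a local-linear smoother of the IPCW-weighted
    alive indicator 1(o_i > t) on the predicted S_i(t), clipped to [0, 1];
    the group mean absolute gap is then integrated over t (trapezoid) and
    divided by tau.
    """
    tau = default_tau(cohort) if tau is None else float(tau)
    censoring = censoring or CensoringDistribution.fit(cohort)
    mask = _group_mask(cohort, group)
    if int(mask.sum()) < 20:
        raise ValueError("ICI needs at least 20 subjects in the group")
    et = cohort.time[(cohort.event == 1) & (cohort.time <= tau)]
    if et.size == 0:
        raise ValueError("no events before tau")
    deciles = np.quantile(et, np.linspace(0.1, 0.9, n_grid - 1))
    grid = np.unique(np.concatenate([[0.0], deciles, [tau]]))
    gaps = np.zeros(grid.size)
    for gi, t in enumerate(grid):
        if t == 0.0:
            continue  # S(0)=1 and everyone alive: zero gap
        S = _curve_at(curves, t)[mask]
        w, _ = ipcw_weights(cohort, censoring, t)
        alive = (cohort.time[mask] > t).astype(float)
        calibrated = np.clip(
            _local_linear_smooth(S, alive, w[mask], span=span), 0.0, 1.0
        )
        gaps[gi] = float(np.mean(np.abs(S - calibrated)))
    return float(np.trapezoid(gaps, grid) / tau)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapCI:
    lower: float
    upper: float
    replicates: int
    skipped: int = 0
    warning: str | None = None


def bootstrap_ci(metric_fn, n: int, B: int = 1000, seed: int = 0) -> BootstrapCI:
    """Percentile 95% CI from B subject resamples.

    ``metric_fn(idx)`` maps a resampled index array to a value or ``None``
    (replicate skipped, e.g. a group absent from the resample). More than
    10% skipped replicates attaches a warning.
    """
    if B < 100:
        raise ValueError("bootstrap needs B >= 100")
    rng = np.random.default_rng(seed)
    values = []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        v = metric_fn(idx)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            skipped += 1
        else:
            values.append(v)
    warning = None
    if skipped > 0.1 * B:
        warning = f"{skipped}/{B} bootstrap replicates skipped"
        logger.warning("bootstrap: %s", warning)
    if not values:
        return BootstrapCI(np.nan, np.nan, 0, skipped, warning or "all replicates skipped")
    lo, hi = np.percentile(values, [2.5, 97.5])
    return BootstrapCI(float(lo), float(hi), len(values), skipped, warning)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

_METRICS = ("within_c", "cross_c", "ibs", "ici")


@dataclass
class FairnessReport:
    """Per-group and overall discrimination/calibration with bootstrap CIs.

    ``rows`` maps a group name (or "Overall") to a metric dict; each metric
    entry is ``{"value": float|None, "ci": [lo, hi]|None, "replicates": int,
    "reason": str|None}``. Defined-missing values stay explicit nulls.
    """

    rows: dict
    n_bootstrap: int
    seed: int

    def to_dict(self) -> dict:
        return {"rows": self.rows, "n_bootstrap": self.n_bootstrap, "seed": self.seed}

    def value(self, group: str, metric: str):
        return self.rows[group][metric]["value"]

    def to_table(self) -> str:
        headers = ["group", "n", "within C", "cross C", "IBS", "ICI"]
        lines = ["\t".join(headers)]
        for name, row in self.rows.items():
            cells = [name, str(row["n"])]
            for m in _METRICS:
                e = row[m]
                if e["value"] is None:
                    cells.append("--")
                elif e["ci"] is not None:
                    cells.append(f"{e['value']:.3f} ({e['ci'][0]:.3f}-{e['ci'][1]:.3f})")
                else:
                    cells.append(f"{e['value']:.3f}")
            lines.append("\t".join(cells))
        return "\n".join(lines)


def _metric_entry(value, ci: BootstrapCI | None = None, reason=None) -> dict:
    return {
        "value": None if value is None else float(value),
        "ci": None if ci is None else [ci.lower, ci.upper],
        "replicates": 0 if ci is None else ci.replicates,
        "reason": reason,
    }


def _all_metrics(scores, curves, cohort, tau, censoring) -> dict:
    """Point values of every metric for every row, computed in one pass."""
    counts = pair_counts(scores, cohort)
    out: dict = {}
    c, tied, tot = counts.all_counts
    out[("Overall", "within_c")] = (c + 0.5 * tied) / tot if tot else None
    out[("Overall", "cross_c")] = None
    try:
        out[("Overall", "ibs")] = integrated_brier(
            curves, cohort, None, tau, censoring)
    except ValueError:
        out[("Overall", "ibs")] = None
    try:
        out[("Overall", "ici")] = integrated_calibration_index(
            curves, cohort, None, tau, censoring)
    except ValueError:
        out[("Overall", "ici")] = None
    for g, name in enumerate(cohort.group_names, start=1):
        if not np.any(cohort.group == g):
            for m in _METRICS:
                out[(name, m)] = None
            continue
        for kind, key in (("within", "within_c"), ("cross", "cross_c")):
            c, tied, tot = getattr(counts, kind)[g]
            out[(name, key)] = (c + 0.5 * tied) / tot if tot else None
        for fn, key in ((integrated_brier, "ibs"),
                        (integrated_calibration_index, "ici")):
            try:
                out[(name, key)] = fn(curves, cohort, g, tau, censoring)
            except ValueError:
                out[(name, key)] = None
    return out


def evaluate(
    model,
    cohort: SurvivalCohort,
    tau: float | None = None,
    n_bootstrap: int = 1000,
    seed: int = 0,
    curves: SurvivalCurve | None = None,
) -> FairnessReport:
    """Assemble the full fairness report for a fitted model on a cohort.

    ``model`` may be a FittedModel (scores predicted, Breslow hazard fit on
    this cohort) or a precomputed RiskOutput/score array. ``n_bootstrap=0``
    skips confidence intervals.
    """
    from .breslow import breslow_fit, predict_survival  # local: avoid cycle at import

    if hasattr(model, "predict"):
        scores = model.predict(cohort).scores
    else:
        scores = _as_scores(model)
    tau = default_tau(cohort) if tau is None else float(tau)
    if curves is None:
        hazard = breslow_fit(scores, cohort)
        grid = _event_grid(cohort, tau, 100)
        curves = predict_survival(scores, hazard, grid)
    censoring = CensoringDistribution.fit(cohort)
    point = _all_metrics(scores, curves, cohort, tau, censoring)

    cis: dict = {}
    if n_bootstrap:
        rng = np.random.default_rng(seed)
        samples: dict = {key: [] for key in point}
        skipped: dict = {key: 0 for key in point}
        for _ in range(n_bootstrap):
            idx = rng.integers(0, cohort.n, size=cohort.n)
            sub = cohort.subset(idx)
            sub_curves = SurvivalCurve(curves.times, curves.probabilities[idx])
            sub_cens = CensoringDistribution.fit(sub)
            vals = _all_metrics(scores[idx], sub_curves, sub, tau, sub_cens)
            for key, v in vals.items():
                if v is None:
                    skipped[key] += 1
                else:
                    samples[key].append(v)
        for key, vals in samples.items():
            if point[key] is None or not vals:
                cis[key] = None
                continue
            lo, hi = np.percentile(vals, [2.5, 97.5])
            warning = None
            if skipped[key] > 0.1 * n_bootstrap:
                warning = f"{skipped[key]}/{n_bootstrap} replicates skipped"
            cis[key] = BootstrapCI(float(lo), float(hi), len(vals),
                                   skipped[key], warning)

    rows: dict = {}
    group_sizes = {"Overall": cohort.n}
    for g, name in enumerate(cohort.group_names, start=1):
        group_sizes[name] = int((cohort.group == g).sum())
    for row_name in ["Overall", *cohort.group_names]:
        row = {"n": group_sizes[row_name]}
        for m in _METRICS:
            v = point[(row_name, m)]
            reason = None
            if v is None:
                reason = ("not defined for the overall row"
                          if (row_name, m) == ("Overall", "cross_c")
                          else "empty pair set or insufficient group data")
            row[m] = _metric_entry(v, cis.get((row_name, m)), reason)
        rows[row_name] = row
    return FairnessReport(rows=rows, n_bootstrap=n_bootstrap, seed=seed)


def cross_group_gap(report: FairnessReport) -> float | None:
    """Max minus min cross-group C-index across groups (the fairness gap)."""
    vals = [report.value(g, "cross_c") for g in report.rows if g != "Overall"]
    vals = [v for v in vals if v is not None]
    if not vals:
        return None
    return float(max(vals) - min(vals))
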