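"""Concordance variants, IPCW Brier score, ICI, bootstrap, report assembly."""

import numpy as np
import pytest
from dataclasses import replace

from fairsurv import (
    ComparablePairSet, SurvivalCohort, SurvivalCurve, SimulationConfig,
    bootstrap_ci, concordance, default_ncdb_like, evaluate, integrated_brier,
    integrated_calibration_index, pair_counts, simulate_cohort, true_survival,
)
from fairsurv.metrics import CensoringDistribution, brier_scores
from tests.conftest import random_cohort


def oracle_concordance(scores, cohort, kind="all", k=0):
    """Exhaustive double-loop concordance, independent of the package path."""
    conc = tied = tot = 0
    for i in range(cohort.n):
        if cohort.event[i] != 1:
            continue
        for j in range(cohort.n):
            if not cohort.time[i] < cohort.time[j]:
                continue
            gi, gj = cohort.group[i], cohort.group[j]
            if kind == "within" and not (gi == k and gj == k):
                continue
            if kind == "cross" and not ((gi == k) != (gj == k)):
                continue
            tot += 1
            if scores[i] > scores[j]:
                conc += 1
            elif scores[i] == scores[j]:
                tied += 1
    return None if tot == 0 else (conc + 0.5 * tied) / tot


class TestConcordance:
    def test_perfect_ranking(self):
        rng = np.random.default_rng(0)
        time = rng.uniform(1, 10, 20)
        cohort = SurvivalCohort(time, np.ones(20, dtype=int), np.ones(20, dtype=int),
                                np.zeros((20, 1)), ("x",), ("g",))
        assert concordance(-time, cohort) == 1.0

    def test_all_tied_scores(self):
        rng = np.random.default_rng(1)
        time = rng.uniform(1, 10, 15)
        cohort = SurvivalCohort(time, np.ones(15, dtype=int), np.ones(15, dtype=int),
                                np.zeros((15, 1)), ("x",), ("g",))
        assert concordance(np.zeros(15), cohort) == 0.5

    def test_five_subject_all_variants_vs_oracle(self, tiny_cohort):
        scores = np.array([0.9, 0.1, 0.5, 0.3, -0.2])
        assert concordance(scores, tiny_cohort) == oracle_concordance(
            scores, tiny_cohort)
        for k in (1, 2):
            for kind in ("within", "cross"):
                got = concordance(scores, tiny_cohort, (kind, k))
                want = oracle_concordance(scores, tiny_cohort, kind, k)
                assert got == want, (kind, k)

    def test_matches_sksurv_on_distinct_times(self):
        from sksurv.metrics import concordance_index_censored
        rng = np.random.default_rng(7)
        n = 200
        cohort = SurvivalCohort(
            rng.uniform(1, 10, n), rng.integers(0, 2, n), rng.integers(1, 3, n),
            rng.standard_normal((n, 1)), ("x",), ("a", "b"))
        scores = rng.standard_normal(n)
        ours = concordance(scores, cohort)
        theirs = concordance_index_censored(
            cohort.event.astype(bool), cohort.time, scores)[0]
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_empty_pair_set_reported_missing(self):
        cohort = SurvivalCohort(
            np.array([1.0, 2.0, 3.0]), np.array([1, 0, 0]), np.array([1, 2, 2]),
            np.zeros((3, 1)), ("x",), ("a", "b"))
        # group b has no events: its within set is empty
        assert concordance(np.zeros(3), cohort, ("within", 2)) is None

    def test_antisymmetry_under_negation(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            cohort = random_cohort(rng, int(rng.integers(8, 40)))
            scores = rng.standard_normal(cohort.n)  # continuous: no ties
            c = concordance(scores, cohort)
            if c is None:
                continue
            assert concordance(-scores, cohort) == pytest.approx(1 - c, abs=1e-12)

    def test_pair_set_partition_identity(self):
        rng = np.random.default_rng(13)
        for trial in range(30):
            cohort = random_cohort(rng, int(rng.integers(5, 50)))
            counts = pair_counts(rng.standard_normal(cohort.n), cohort)
            total = counts.all_counts[2]
            within = sum(v[2] for v in counts.within.values())
            cross = sum(v[2] for v in counts.cross.values())
            assert total == within + cross / 2


class TestComparablePairSet:
    def test_pair_invariants(self, tiny_cohort):
        allp = ComparablePairSet.build(tiny_cohort, "all")
        for i, j in allp.pairs:
            assert tiny_cohort.time[i] < tiny_cohort.time[j]
            assert tiny_cohort.event[i] == 1
        cross = ComparablePairSet.build(tiny_cohort, ("cross", 1))
        for i, j in cross.pairs:
            assert (tiny_cohort.group[i] == 1) != (tiny_cohort.group[j] == 1)
        within = ComparablePairSet.build(tiny_cohort, ("within", 1))
        for i, j in within.pairs:
            assert tiny_cohort.group[i] == tiny_cohort.group[j] == 1


def _no_censor_cohort(rng, n):
    return SurvivalCohort(
        rng.uniform(1, 10, n), np.ones(n, dtype=int), np.ones(n, dtype=int),
        np.zeros((n, 1)), ("x",), ("g",))


class TestIntegratedBrier:
    def test_perfect_oracle_predictions_zero(self):
        rng = np.random.default_rng(2)
        cohort = _no_censor_cohort(rng, 40)
        grid = np.unique(cohort.time)
        # S_i(t) = 1(o_i > t): exact step-function knowledge of each outcome
        probs = (cohort.time[:, None] > grid[None, :]).astype(float)
        curves = SurvivalCurve(grid, probs)
        assert integrated_brier(curves, cohort, tau=grid[-1]) == pytest.approx(0.0)

    def test_constant_half_prediction_quarter(self):
        rng = np.random.default_rng(3)
        cohort = _no_censor_cohort(rng, 30)
        # S(t) = 0.5 on the whole horizon, including t=0
        grid = np.concatenate([[0.0], np.unique(cohort.time)[:-1]])
        curves = SurvivalCurve(grid, np.full((30, grid.size), 0.5))
        tau = grid[-1]
        assert integrated_brier(curves, cohort, tau=tau) == pytest.approx(0.25)

    def test_censored_instance_vs_hand_ipcw_sum(self):
        # 6 subjects, 2 censored; independent double sum with hand-built
        # censoring KM and trapezoid
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 0, 1, 1, 0, 1])
        cohort = SurvivalCohort(time, event, np.ones(6, dtype=int),
                                np.zeros((6, 1)), ("x",), ("g",))
        rng = np.random.default_rng(4)
        grid = np.array([0.0, 1.5, 2.5, 3.5, 4.5, 5.5])
        probs = np.clip(rng.uniform(0.1, 1.0, (6, grid.size)), 0, 1)
        probs = np.sort(probs, axis=1)[:, ::-1]  # make non-increasing
        curves = SurvivalCurve(grid, probs)
        tau = 5.5

        # censoring KM: censoring events at t=2 (5 at risk) and t=5 (2 at risk)
        def G(t):
            g = 1.0
            if t >= 2.0:
                g *= 1 - 1 / 5
            if t >= 5.0:
                g *= 1 - 1 / 2
            return g

        def G_minus(t):
            return G(t - 1e-9)

        # integration grid: {0} + unique event times <= tau + {tau}
        igrid = np.array([0.0, 1.0, 3.0, 4.0, tau])
        bs = []
        for t in igrid:
            total = 0.0
            for i in range(6):
                k = np.searchsorted(grid, t, side="right") - 1
                Si = probs[i, k] if k >= 0 else 1.0
                if event[i] == 1 and time[i] <= t:
                    total += (0 - Si) ** 2 / G_minus(time[i])
                elif time[i] > t:
                    total += (1 - Si) ** 2 / G(t)
            bs.append(total / 6)
        expected = np.trapezoid(bs, igrid) / tau
        got = integrated_brier(curves, cohort, tau=tau)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_matches_sksurv_brier_score(self):
        from sksurv.metrics import brier_score as sks_brier
        from sksurv.util import Surv
        rng = np.random.default_rng(5)
        n = 400
        cohort = SurvivalCohort(
            rng.uniform(1, 10, n), rng.integers(0, 2, n), np.ones(n, dtype=int),
            rng.standard_normal((n, 1)), ("x",), ("g",))
        from fairsurv import breslow_fit, predict_survival
        scores = 0.5 * cohort.covariates[:, 0]
        hz = breslow_fit(scores, cohort)
        times = np.quantile(cohort.time, [0.3, 0.5, 0.7])
        curves = predict_survival(scores, hz, times)
        ours = brier_scores(curves, cohort, times)
        y = Surv.from_arrays(cohort.event.astype(bool), cohort.time)
        _, theirs = sks_brier(y, y, curves.probabilities, times)
        np.testing.assert_allclose(ours, theirs, atol=1e-10)


class TestICI:
    @staticmethod
    def _frailty_free(n, seed):
        return SimulationConfig(
            n=n, group_probs=np.array([0.7, 0.3]), baseline_shape=1.0,
            baseline_scale=5.0, beta=np.array([0.6, -0.4]),
            group_log_hr=np.array([0.0, 0.4]), censor_rate=0.05,
            admin_time=12.0, seed=seed,
        )

    def test_true_probabilities_nearly_perfectly_calibrated(self):
        cfg = self._frailty_free(20_000, 6)
        cohort, _ = simulate_cohort(cfg)
        tau = np.quantile(cohort.time, 0.9)
        grid = np.linspace(0.01, tau, 30)
        probs = true_survival(cfg, cohort.covariates, cohort.group, grid)
        curves = SurvivalCurve(grid, probs)
        ici = integrated_calibration_index(curves, cohort, tau=tau)
        assert ici < 0.02

    def test_downshifted_predictions_show_offset(self):
        # predictions = truth - 0.2 (clipped): the calibration gap recovers
        # the planted offset up to clipping and smoother tolerance
        cfg = self._frailty_free(8_000, 8)
        cohort, _ = simulate_cohort(cfg)
        tau = np.quantile(cohort.time, 0.5)
        grid = np.linspace(0.01, tau, 15)
        probs = true_survival(cfg, cohort.covariates, cohort.group, grid)
        shifted = np.clip(probs - 0.2, 0.0, 1.0)
        curves = SurvivalCurve(grid, shifted)
        ici = integrated_calibration_index(curves, cohort, tau=tau)
        assert 0.15 < ici < 0.25

    def test_single_time_constant_predictions_hand_computed(self):
        # degenerate predictions: calibration is the IPCW-weighted empirical
        # survival; gap = |0.7 - weighted mean alive| at the single time
        time = np.array([1.0, 2.0, 3.0, 4.0] * 6)
        event = np.array([1, 1, 0, 1] * 6)
        n = time.size
        cohort = SurvivalCohort(time, event, np.ones(n, dtype=int),
                                np.zeros((n, 1)), ("x",), ("g",))
        t0 = 2.5
        curves = SurvivalCurve(np.array([0.0]), np.full((n, 1), 0.7))
        cens = CensoringDistribution.fit(cohort)
        from fairsurv.metrics import ipcw_weights

        # replicate the documented grid: {0} + event-time quantiles + {tau}
        et = time[(event == 1) & (time <= t0)]
        grid = np.unique(np.concatenate(
            [[0.0], np.quantile(et, np.linspace(0.1, 0.9, 1)), [t0]]))
        gaps = []
        for t in grid:
            if t == 0.0:
                gaps.append(0.0)
                continue
            w, _ = ipcw_weights(cohort, cens, t)
            alive = (time > t).astype(float)
            gaps.append(abs(0.7 - np.average(alive[w > 0], weights=w[w > 0])))
        expected = np.trapezoid(gaps, grid) / t0
        ici = integrated_calibration_index(curves, cohort, tau=t0, n_grid=2)
        assert ici == pytest.approx(expected, rel=1e-9)

    def test_small_group_rejected(self):
        rng = np.random.default_rng(9)
        cohort = _no_censor_cohort(rng, 10)
        curves = SurvivalCurve(np.array([1.0]), np.full((10, 1), 0.5))
        with pytest.raises(ValueError, match="20 subjects"):
            integrated_calibration_index(curves, cohort, tau=1.0)


class TestBootstrap:
    def test_constant_metric_degenerate_interval(self):
        ci = bootstrap_ci(lambda idx: 0.42, n=50, B=100, seed=0)
        assert ci.lower == ci.upper == 0.42

    def test_seed_determinism(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(100)
        fn = lambda idx: float(np.mean(x[idx]))
        a = bootstrap_ci(fn, n=100, B=200, seed=5)
        b = bootstrap_ci(fn, n=100, B=200, seed=5)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_skipped_replicates_warning(self):
        calls = iter(range(10_000))
        fn = lambda idx: None if next(calls) % 5 == 0 else 1.0
        ci = bootstrap_ci(fn, n=20, B=100, seed=1)
        assert ci.skipped > 10 and ci.warning is not None

    def test_cindex_ci_width_shrinks_with_n(self):
        widths = []
        for n in (500, 2000, 8000):
            cohort, _ = simulate_cohort(replace(
                self_cfg(), n=n, seed=17))
            scores = cohort.covariates @ np.array([0.6, -0.4])
            fn = lambda idx: concordance(scores[idx], cohort.subset(idx))
            ci = bootstrap_ci(fn, n=n, B=200, seed=2)
            widths.append(ci.upper - ci.lower)
        assert widths[0] > widths[1] > widths[2]
        # roughly 1/sqrt(n): a 16-fold n increase shrinks width ~4-fold
        assert widths[0] / widths[2] > 2.0


def self_cfg():
    return SimulationConfig(
        n=500, group_probs=np.array([1.0]), baseline_shape=1.0,
        baseline_scale=5.0, beta=np.array([0.6, -0.4]),
        group_log_hr=np.array([0.0]), censor_rate=0.05, seed=0,
    )


@pytest.fixture(scope="module")
def report_and_cohort():
    cohort, _ = simulate_cohort(default_ncdb_like(seed=2, n=2500))
    rng = np.random.default_rng(0)
    scores = cohort.covariates @ rng.standard_normal(cohort.p) * 0.3
    report = evaluate(scores, cohort, n_bootstrap=0)
    return report, cohort, scores


class TestEvaluate:
    def test_shape_contract(self, report_and_cohort):
        report, cohort, _ = report_and_cohort
        assert set(report.rows) == {"Overall", *cohort.group_names}
        for row in report.rows.values():
            assert {"within_c", "cross_c", "ibs", "ici"} <= set(row)

    def test_overall_equals_all_pairs_concordance(self, report_and_cohort):
        report, cohort, scores = report_and_cohort
        assert report.value("Overall", "within_c") == pytest.approx(
            concordance(scores, cohort))

    def test_missing_values_are_explicit(self, report_and_cohort):
        report, _, _ = report_and_cohort
        entry = report.rows["Overall"]["cross_c"]
        assert entry["value"] is None and entry["reason"]

    def test_bootstrap_cis_bracket_point_estimates(self):
        cohort, _ = simulate_cohort(default_ncdb_like(seed=3, n=600))
        scores = cohort.covariates[:, 0] * 0.5
        report = evaluate(scores, cohort, n_bootstrap=100, seed=0)
        for row_name in report.rows:
            e = report.rows[row_name]["within_c"]
            if e["value"] is None or e["ci"] is None:
                continue
            assert e["ci"][0] <= e["ci"][1]
            # percentile CIs from moderate B should surround the estimate
            assert e["ci"][0] - 0.1 <= e["value"] <= e["ci"][1] + 0.1
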