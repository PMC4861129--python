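"""Quantile partition, log-rank test, univariate Cox, threshold scan."""

import numpy as np
import pandas as pd
import pytest

from metsig import (
    MetsigError,
    cox_univariate,
    logrank_from_arrays,
    logrank_test,
    partition_by_score,
    threshold_scan,
)
def random_survival_data(rng, n, with_ties=False):
    """Random censored survival data for cross-checks."""
    time = rng.exponential(5.0, size=n)
    if with_ties:
        time = np.round(time, 1) + 0.1  # coarse grid forces tied event times
    event = (rng.random(n) < 0.7).astype(float)
    if event.sum() == 0:
        event[0] = 1.0
    group = rng.random(n) < 0.5
    if group.all() or not group.any():
        group[0] = ~group[0]
    return time, event, group


def _scores(n, values=None):
    idx = [f"S{i:04d}" for i in range(n)]
    vals = values if values is not None else np.arange(n, dtype=float)
    return pd.Series(vals, index=idx, name="score")


class TestPartition:
    @pytest.mark.parametrize(
        "n,f_low,f_high,n_low,n_high",
        [
            (377, 0.25, 0.75, 95, 282),  # bottom quartile of the 377-specimen cohort
            (4, 0.25, 0.75, 1, 3),
            (9, 1 / 3, 1 / 3, 3, 3),
        ],
    )
    def test_ceiling_rule(self, n, f_low, f_high, n_low, n_high):
        g = partition_by_score(_scores(n), f_low, f_high)
        assert (len(g.low_ids), len(g.high_ids)) == (n_low, n_high)

    def test_complement_partition_when_fractions_sum_to_one(self):
        for n in range(2, 40):
            g = partition_by_score(_scores(n), 0.25, 0.75)
            assert len(g.low_ids) + len(g.high_ids) == n
            assert not set(g.low_ids) & set(g.high_ids)

    def test_middle_unassigned_for_non_adjacent_groups(self):
        g = partition_by_score(_scores(9), 1 / 3, 1 / 3)
        assert len(set(g.low_ids) | set(g.high_ids)) == 6

    def test_overlapping_fractions_rejected(self):
        with pytest.raises(MetsigError, match="overlap"):
            partition_by_score(_scores(10), 0.6, 0.6)

    def test_ties_broken_by_specimen_id(self):
        scores = pd.Series([1.0, 1.0, 1.0, 2.0], index=["d", "b", "a", "c"])
        g = partition_by_score(scores, 0.5, 0.5)
        # sort key (score, id): a(1) b(1) d(1) c(2) -> low {a,b}, high {d,c}
        assert g.low_ids == ["a", "b"] and g.high_ids == ["d", "c"]


class TestLogRank:
    def test_hand_computed_example(self, toy_survival):
        res = logrank_from_arrays(
            toy_survival["time"].to_numpy(),
            toy_survival["event"].to_numpy(),
            np.array([False, False, True, True]),
        )
        # O_L=2, E_L=5/6, V=17/36 -> chi2 = 49/17
        assert res.chi_square == pytest.approx(49 / 17, abs=1e-12)
        assert res.p == pytest.approx(0.0895, abs=2e-4)
        assert res.direction == -1  # high-score group had fewer deaths than expected

    def test_identical_groups_null(self):
        time = np.array([1.0, 2.0, 1.0, 2.0])
        event = np.ones(4)
        res = logrank_from_arrays(time, event, np.array([False, False, True, True]))
        assert res.chi_square == 0.0 and res.p == 1.0

    def test_time_scale_invariance(self):
        rng = np.random.default_rng(5)
        time, event, group = random_survival_data(rng, 60)
        a = logrank_from_arrays(time, event, group)
        b = logrank_from_arrays(time * 10.0, event, group)
        assert a.chi_square == pytest.approx(b.chi_square, abs=1e-12)

    def test_no_events_raises(self):
        with pytest.raises(MetsigError, match="no events"):
            logrank_from_arrays(np.array([1.0, 2.0]), np.zeros(2), np.array([True, False]))

    def test_empty_group_raises(self):
        with pytest.raises(MetsigError, match="empty"):
            logrank_from_arrays(np.array([1.0, 2.0]), np.ones(2), np.array([True, True]))

    def test_matches_lifelines_on_random_data_with_ties(self):
        """Agreement with an independent survival implementation to 1e-8."""
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(20, 80))
            time, event, group = random_survival_data(rng, n, with_ties=True)
            ours = logrank_from_arrays(time, event, group)
            ref = ll_logrank(time[group], time[~group], event[group], event[~group])
            assert ours.chi_square == pytest.approx(ref.test_statistic, abs=1e-8)
            assert ours.p == pytest.approx(ref.p_value, abs=1e-8)

    def test_logrank_test_uses_partition_groups(self, toy_survival):
        groups = partition_by_score(
            pd.Series([0.0, 1.0, 2.0, 3.0], index=["a", "b", "c", "d"]), 0.5, 0.5
        )
        res = logrank_test(groups, toy_survival)
        assert res.chi_square == pytest.approx(49 / 17, abs=1e-12)


class TestCox:
    def test_score_test_equals_logrank_for_binary_covariate(self):
        rng = np.random.default_rng(2)
        time = rng.exponential(2.0, 40)  # continuous: no ties
        event = np.ones(40)
        group = rng.random(40) < 0.4
        surv = pd.DataFrame({"time": time, "event": event},
                            index=[f"P{i}" for i in range(40)])
        _, _, _, p_score = cox_univariate(group.astype(float), surv)
        lr = logrank_from_arrays(time, event, group)
        assert p_score == pytest.approx(lr.p, abs=1e-10)

    def test_negating_covariate_negates_beta(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        time = rng.exponential(np.exp(-0.5 * x))
        surv = pd.DataFrame({"time": time, "event": np.ones(50)},
                            index=[f"P{i}" for i in range(50)])
        b1, _, pw1, ps1 = cox_univariate(x, surv)
        b2, _, pw2, ps2 = cox_univariate(-x, surv)
        assert b1 == pytest.approx(-b2, abs=1e-8)
        assert pw1 == pytest.approx(pw2, abs=1e-10) and ps1 == pytest.approx(ps2, abs=1e-12)

    def test_matches_lifelines_estimate(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(4)
        x = rng.normal(size=120)
        time = rng.exponential(np.exp(-0.8 * x))
        event = (rng.random(120) < 0.8).astype(float)
        surv = pd.DataFrame({"time": time, "event": event},
                            index=[f"P{i}" for i in range(120)])
        beta, se, _, _ = cox_univariate(x, surv)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"x": x, "T": time, "E": event}), "T", "E"
        )
        assert beta == pytest.approx(cph.params_["x"], abs=1e-6)
        assert se == pytest.approx(cph.standard_errors_["x"], abs=1e-6)

    def test_score_test_calibrated_under_null(self):
        """Independent covariate: ~5% rejections at alpha 0.05."""
        rng = np.random.default_rng(6)
        rejections = 0
        reps = 300
        for _ in range(reps):
            n = 40
            x = rng.normal(size=n)
            surv = pd.DataFrame(
                {"time": rng.exponential(1.0, n), "event": np.ones(n)},
                index=[f"P{i}" for i in range(n)],
            )
            _, _, _, p_score = cox_univariate(x, surv)
            rejections += p_score < 0.05
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 4 * se

    def test_constant_covariate_rejected(self):
        surv = pd.DataFrame({"time": [1.0, 2.0], "event": [1.0, 1.0]}, index=["a", "b"])
        with pytest.raises(MetsigError, match="constant"):
            cox_univariate(np.array([1.0, 1.0]), surv)


class TestThresholdScan:
    def test_singleton_grid_reduces_to_logrank(self, toy_survival):
        scores = pd.Series([0.0, 1.0, 2.0, 3.0], index=["a", "b", "c", "d"])
        scan = threshold_scan(scores, toy_survival, [(0.5, 0.5)])
        assert len(scan) == 1
        assert scan.loc[0, "chi_square"] == pytest.approx(49 / 17, abs=1e-12)

    def test_planted_hazard_direction_consistent_across_grid(self):
        from metsig import SimulationConfig, generate_expression_cohort, signature_score
        from metsig.datatypes import IntegratedSignature

        cfg = SimulationConfig(n_specimens=400, hazard_coefficient=1.5,
                               censoring_rate=0.3, seed=11)
        cohort, _ = generate_expression_cohort(cfg)
        sig = IntegratedSignature.from_fold_changes(
            pd.Series({g: +1.0 for g in cfg.signature_genes_up}
                      | {g: -1.0 for g in cfg.signature_genes_down})
        )
        surv = cohort.survival_records()
        scores = signature_score(cohort.expression[list(surv.index)], sig)["score"]
        scan = threshold_scan(scores, surv)
        assert not scan["failed"].any()
        assert (scan["direction"] == 1).all()  # high score = worse survival

    def test_constant_scores_flagged_degenerate(self, toy_survival):
        scores = pd.Series([1.0, 1.0, 1.0, 1.0], index=["a", "b", "c", "d"])
        scan = threshold_scan(scores, toy_survival)
        assert scan["failed"].all()
        assert scan["error"].str.contains("degenerate").all()

    def test_empty_grid_rejected(self, toy_survival):
        with pytest.raises(MetsigError, match="empty"):
            threshold_scan(pd.Series([1.0], index=["a"]), toy_survival, [])
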