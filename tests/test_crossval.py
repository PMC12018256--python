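"""Staggered fold assignment, window-overlap exclusion, metric suite."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tfo.crossval import (
    N_FOLDS,
    assign_folds,
    evaluate,
    exclude_overlap,
    run_cross_validation,
)
from tfo.fusion import TrainConfig
from tfo.simulate import simulate_feature_cohort


class TestAssignFolds:
    def test_first_round_first_iteration(self):
        # l=100, round position 0, iteration 0: validation = samples 1..20
        a = assign_folds({"r1": 100}, 0)[0]
        np.testing.assert_array_equal(a.val_idx, np.arange(0, 20))

    def test_second_round_staggered_start(self):
        # round position 1 starts at 20 %: validation = samples 21..40
        a = assign_folds({"r1": 100, "r2": 100}, 0)[1]
        np.testing.assert_array_equal(a.val_idx, np.arange(20, 40))

    def test_last_iteration_wraps_and_covers(self):
        # round position 0, iteration 4: validation = samples 81..100
        a = assign_folds({"r1": 100}, 4)[0]
        np.testing.assert_array_equal(a.val_idx, np.arange(80, 100))
        covered = np.concatenate(
            [assign_folds({"r1": 100}, j)[0].val_idx for j in range(N_FOLDS)]
        )
        np.testing.assert_array_equal(np.sort(covered), np.arange(100))

    def test_round_order_determines_stagger(self):
        ab = assign_folds({"a": 100, "b": 100}, 0)
        ba = assign_folds({"b": 100, "a": 100}, 0)
        np.testing.assert_array_equal(ab[0].val_idx, ba[0].val_idx)
        assert ab[0].round_id == "a" and ba[0].round_id == "b"

    def test_short_round_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            assign_folds({"r1": 4}, 0)

    @given(length=st.integers(5, 5000), pos=st.integers(0, 7))
    @settings(max_examples=100, deadline=None)
    def test_partition_properties_for_arbitrary_length(self, length, pos):
        rounds = {f"r{i}": length for i in range(pos + 1)}
        val_sets = []
        for j in range(N_FOLDS):
            a = assign_folds(rounds, j)[pos]
            # contiguity
            if a.val_idx.size:
                assert np.all(np.diff(a.val_idx) == 1)
            # disjoint from training
            assert not np.intersect1d(a.val_idx, a.train_idx).size
            # together they cover the round
            both = np.sort(np.concatenate([a.val_idx, a.train_idx]))
            np.testing.assert_array_equal(both, np.arange(length))
            val_sets.append(a.val_idx)
        # each index validated exactly once across the five iterations
        allv = np.sort(np.concatenate(val_sets))
        np.testing.assert_array_equal(allv, np.arange(length))


class TestExcludeOverlap:
    def _assignment(self, n, val_lo, val_hi):
        val = np.arange(val_lo, val_hi)
        train = np.setdiff1d(np.arange(n), val)
        from tfo.crossval import FoldAssignment

        return FoldAssignment(
            round_id=0, iteration=0, start_fraction=0.0, val_idx=val, train_idx=train
        )

    def test_centered_windows_discard_neighbours_of_validation_block(self):
        # samples at t = 0..299 s, windows t +/- 45 s, validation t in [100, 200]
        t = np.arange(300.0)
        a = self._assignment(300, 100, 201)
        out = exclude_overlap(a, t - 45.0, t + 45.0)
        discarded_t = t[out.discarded_idx]
        expected = np.concatenate([np.arange(11.0, 100.0), np.arange(201.0, 290.0)])
        np.testing.assert_array_equal(np.sort(discarded_t), expected)

    def test_zero_width_windows_discard_nothing(self):
        t = np.arange(300.0)
        a = self._assignment(300, 100, 201)
        out = exclude_overlap(a, t, t)
        assert out.discarded_idx.size == 0

    def test_no_validation_overlap_after_exclusion(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 1000, 400))
        a = self._assignment(400, 150, 230)
        out = exclude_overlap(a, t - 45.0, t + 45.0)
        for i in out.train_idx:
            for j in out.val_idx:
                lo = max(t[i] - 45.0, t[j] - 45.0)
                hi = min(t[i] + 45.0, t[j] + 45.0)
                assert lo >= hi, (i, j)

    def test_training_preserved_away_from_validation(self):
        t = np.arange(300.0)
        a = self._assignment(300, 100, 201)
        out = exclude_overlap(a, t - 45.0, t + 45.0)
        kept_t = t[out.train_idx]
        assert (kept_t <= 10.0).sum() == 11
        assert (kept_t >= 290.0).sum() == 10


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([1, 1, 0, 0, 1], dtype=bool)
        rep = evaluate(np.where(y, 0.9, 0.1), y, n_bootstrap=10)
        for m in ("accuracy", "sensitivity", "specificity", "precision", "f1", "auc"):
            assert getattr(rep, m) == pytest.approx(1.0)

    def test_hand_computed_confusion_matrix(self):
        # TP=8, FN=2, TN=7, FP=3
        y = np.array([1] * 10 + [0] * 10, dtype=bool)
        prob = np.array([0.9] * 8 + [0.1] * 2 + [0.2] * 7 + [0.8] * 3)
        rep = evaluate(prob, y, n_bootstrap=10)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (8, 2, 7, 3)
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.sensitivity == pytest.approx(0.8)
        assert rep.specificity == pytest.approx(0.7)
        assert rep.precision == pytest.approx(8 / 11)
        assert rep.f1 == pytest.approx(16 / 21)
        assert rep.n == 20

    def test_random_predictions_auc_near_half(self):
        rng = np.random.default_rng(0)
        y = rng.random(4000) > 0.5
        prob = rng.random(4000)
        rep = evaluate(prob, y, n_bootstrap=10)
        assert rep.auc == pytest.approx(0.5, abs=0.03)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        y = rng.random(500) > 0.3
        prob = np.clip(rng.normal(0.5 + 0.2 * y, 0.2), 1e-6, 1 - 1e-6)
        a = evaluate(prob, y, n_bootstrap=10).auc
        b = evaluate(1 / (1 + np.exp(-5 * (prob - 0.5))), y, n_bootstrap=10).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_reports_nan_with_warning(self):
        y = np.ones(10, dtype=bool)
        with pytest.warns(UserWarning, match="single-class"):
            rep = evaluate(np.full(10, 0.8), y, n_bootstrap=10)
        assert np.isnan(rep.specificity)
        assert np.isnan(rep.auc)
        assert rep.sensitivity == 1.0

    def test_bootstrap_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(2)
        y = rng.random(300) > 0.5
        prob = np.clip(0.5 + 0.3 * (y - 0.5) + rng.normal(0, 0.2, 300), 0, 1)
        rep = evaluate(prob, y, n_bootstrap=200, seed=0)
        assert rep.auc_ci[0] < rep.auc < rep.auc_ci[1]

    def test_empty_validation_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate(np.empty(0), np.empty(0, dtype=bool))


class TestRunCrossValidation:
    @pytest.fixture(scope="class")
    def quick_result(self):
        df = simulate_feature_cohort(seed=0)
        cfg = TrainConfig(seed=0, max_epochs=60)
        return df, run_cross_validation(df, train_config=cfg, n_bootstrap=10)

    def test_five_iterations_with_count_table(self, quick_result):
        _, res = quick_result
        assert len(res.reports) == 5
        assert list(res.counts["iteration"]) == [1, 2, 3, 4, 5]
        expected_cols = {
            "hypoxemic_val", "hypoxemic_train", "normoxemic_val", "normoxemic_train",
            "accuracy", "sensitivity", "specificity", "precision", "f1",
        }
        assert expected_cols <= set(res.counts.columns)

    def test_validation_counts_cover_all_valid_samples(self, quick_result):
        df, res = quick_result
        n_valid = int(df["valid"].sum())
        total_val = int(
            (res.counts["hypoxemic_val"] + res.counts["normoxemic_val"]).sum()
        )
        assert total_val == n_valid

    def test_no_window_overlap_between_train_and_validation(self, quick_result):
        df, res = quick_result
        valid = df[df["valid"]].sort_values(["round_id", "t"]).reset_index(drop=True)
        for assignments in res.assignments:
            for a in assignments:
                sub = valid[valid["round_id"] == a.round_id]
                ws = sub["win_start"].to_numpy()
                we = sub["win_end"].to_numpy()
                tr_s, tr_e = ws[a.train_idx], we[a.train_idx]
                va_lo, va_hi = ws[a.val_idx].min(), we[a.val_idx].max()
                overlap = (tr_s < va_hi) & (tr_e > va_lo)
                # within the contiguous validation block every window is
                # covered, so the hull comparison is exact here
                assert not overlap.any()

    def test_summary_is_mean_of_iterations(self, quick_result):
        _, res = quick_result
        accs = [r.accuracy for r in res.reports]
        assert res.summary["accuracy"] == pytest.approx(np.nanmean(accs))

    def test_learns_the_synthetic_cohort(self, quick_result):
        _, res = quick_result
        assert res.summary["accuracy"] > 0.8
        assert res.summary["auc"] > 0.9
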