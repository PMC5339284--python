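"""Evaluation protocol: splits, confusion metrics, ROC/AUROC, ANOVA+Tukey."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegfatigue import (
    FeatureMatrix,
    anova_tukey,
    compare_classifiers,
    confusion_metrics,
    holdout_split,
    kfold_split,
    make_classifier,
    q_critical,
    roc_curve,
)


class TestHoldoutSplit:
    def test_6278_gives_printed_sizes(self):
        tr, va, te = holdout_split(6278, seed=0)
        assert (len(tr), len(va), len(te)) == (2093, 2093, 2092)

    def test_minimum_n(self):
        tr, va, te = holdout_split(3, seed=1)
        assert (len(tr), len(va), len(te)) == (1, 1, 1)
        with pytest.raises(ValueError):
            holdout_split(2, seed=1)

    def test_partition_contract(self):
        tr, va, te = holdout_split(101, seed=5)
        allidx = np.sort(np.concatenate([tr, va, te]))
        np.testing.assert_array_equal(allidx, np.arange(101))

    def test_subjectwise_mode_keeps_groups_together(self):
        groups = np.repeat(np.arange(12), 9)  # 12 subjects x 9 segments
        tr, va, te = holdout_split(len(groups), seed=3, groups=groups)
        sets = [set(groups[tr]), set(groups[va]), set(groups[te])]
        assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) and not (sets[1] & sets[2])
        allidx = np.sort(np.concatenate([tr, va, te]))
        np.testing.assert_array_equal(allidx, np.arange(len(groups)))


class TestKFold:
    def test_6278_threefold_sizes(self):
        folds = kfold_split(6278, 3, seed=0)
        assert sorted(len(f) for f in folds) == [2092, 2093, 2093]

    def test_singleton_folds_and_partition(self):
        folds = kfold_split(5, 5, seed=2)
        assert all(len(f) == 1 for f in folds)
        np.testing.assert_array_equal(np.sort(np.concatenate(folds)), np.arange(5))

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            kfold_split(4, 5, seed=0)
        with pytest.raises(ValueError):
            kfold_split(4, 1, seed=0)


class TestConfusionMetrics:
    def test_printed_sparse_dbn_column(self):
        # TP=982, FN=64, TN=965, FP=81
        y_true = np.array([1] * 1046 + [0] * 1046)
        y_pred = np.array([1] * 982 + [0] * 64 + [0] * 965 + [1] * 81)
        rep = confusion_metrics(y_true, y_pred)
        assert round(rep.sensitivity, 1) == 93.9
        assert round(rep.specificity, 1) == 92.3
        assert round(rep.accuracy, 1) == 93.1

    def test_printed_dbn_column_accuracy(self):
        y_true = np.array([1] * 1046 + [0] * 1046)
        y_pred = np.array([1] * 950 + [0] * 96 + [0] * 946 + [1] * 100)
        assert round(confusion_metrics(y_true, y_pred).accuracy, 1) == 90.6

    def test_perfect_prediction(self):
        rep = confusion_metrics([1, 0, 1], [1, 0, 1])
        assert (rep.sensitivity, rep.specificity, rep.accuracy) == (100.0, 100.0, 100.0)

    def test_balanced_classes_accuracy_identity(self):
        """With equal positives and negatives, acc = (sens + spec) / 2."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            y_true = np.repeat([0, 1], 50)
            y_pred = rng.integers(0, 2, 100)
            rep = confusion_metrics(y_true, y_pred)
            assert rep.accuracy == pytest.approx((rep.sensitivity + rep.specificity) / 2)
        assert (93.9 + 92.3) / 2 == pytest.approx(93.1)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_metrics([], [])
        with pytest.raises(ValueError, match="binary"):
            confusion_metrics([0, 2], [0, 1])


class TestROC:
    def test_perfect_separation(self):
        _, auroc = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auroc == 1.0

    def test_constant_scores_give_half(self):
        pts, auroc = roc_curve([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auroc == 0.5
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)

    def test_curve_monotone_and_anchored(self):
        rng = np.random.default_rng(4)
        pts, _ = roc_curve(rng.random(50), rng.integers(0, 2, 50))
        xs, ys = zip(*pts)
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
        assert all(b >= a for a, b in zip(xs, xs[1:]))
        assert all(b >= a for a, b in zip(ys, ys[1:]))

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="positive"):
            roc_curve([0.1, 0.2], [1, 1])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_auroc_equals_mann_whitney_pair_count(self, seed):
        """AUROC == (#concordant + 0.5 #tied) / (n1 * n0), brute force."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        y = rng.integers(0, 2, n)
        if len(set(y)) < 2:
            y[0], y[1] = 0, 1
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        _, auroc = roc_curve(scores, y)
        pos, neg = scores[y == 1], scores[y == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auroc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_auroc_agrees_with_reference_implementation(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        s = rng.random(200)
        _, auroc = roc_curve(s, y)
        assert auroc == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestAnovaTukey:
    def test_critical_values_for_4_groups_df8(self):
        assert q_critical(4, 8, 0.05) == 4.5293
        assert q_critical(4, 8, 0.01) == 6.2044

    def test_identical_groups_nothing_significant(self):
        res = anova_tukey({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]})
        assert res.F == 0.0
        assert all(q == 0.0 and tier == "ns" for _, q, tier in res.pairwise)

    def test_three_group_hand_calculation(self):
        """Integer example checked long-hand against the ANOVA identities."""
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "c": [6.0, 7.0, 8.0]}
        res = anova_tukey(groups)
        # means 2, 3, 7; grand mean 4; SSB = 3*(4+1+9) = 42; SSW = 2+2+2 = 6
        # F = (42/2) / (6/6) = 21
        assert res.F == pytest.approx(21.0)
        assert res.msw == pytest.approx(1.0)
        # Q(a,c) = |2-7| / sqrt(1/3)
        q_ac = [q for pair, q, _ in res.pairwise if pair == ("a", "c")][0]
        assert q_ac == pytest.approx(5.0 / np.sqrt(1.0 / 3.0))

    def test_anova_sum_of_squares_identity(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            data = {f"g{i}": rng.normal(i, 1, 5) for i in range(4)}
            arrs = list(data.values())
            grand = np.concatenate(arrs).mean()
            ss_total = sum(((a - grand) ** 2).sum() for a in arrs)
            ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
            res = anova_tukey(data)
            ss_within = res.msw * res.df_error
            assert ss_total == pytest.approx(ss_between + ss_within, abs=1e-9)

    def test_group_validation(self):
        with pytest.raises(ValueError, match="two groups"):
            anova_tukey({"a": [1, 2]})
        with pytest.raises(ValueError, match="equal-sized"):
            anova_tukey({"a": [1, 2], "b": [1, 2, 3]})
        with pytest.raises(ValueError, match="at least two obs"):
            anova_tukey({"a": [1], "b": [2]})

    def test_q_lookup_validation(self):
        with pytest.raises(ValueError, match="alpha"):
            q_critical(4, 8, 0.1)
        with pytest.raises(ValueError, match="n_groups"):
            q_critical(12, 8, 0.05)


def separable_features(n=120, d=6, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, d)) + 2.5 * y[:, None]
    perm = rng.permutation(n)
    return FeatureMatrix(X[perm], y[perm], [f"f{i}" for i in range(d)])


class TestCompareClassifiers:
    def test_holdout_single_classifier(self):
        fm = separable_features()
        clf = {"ann": make_classifier("ann", seed=1, hidden=[4], eta=5.0,
                                      max_epoch=200, batch_size=20)}
        report = compare_classifiers(fm, clf, protocol="holdout", seed=1)
        assert set(report.reports) == {"ann"}
        rep = report.reports["ann"]
        assert rep.accuracy >= 90.0
        assert rep.auroc is not None

    def test_kfold_produces_per_fold_and_tukey(self):
        fm = separable_features(n=150)
        clfs = {
            "ann": make_classifier("ann", seed=2, hidden=[4], eta=5.0,
                                   max_epoch=30, batch_size=20),
            "sparse-dbn": make_classifier("sparse-dbn", seed=2, hidden=[4, 4],
                                          max_epoch=30),
        }
        report = compare_classifiers(fm, clfs, protocol="kfold", seed=2, k=3)
        assert all(len(r.per_fold) == 3 for r in report.reports.values())
        assert report.tukey is not None
        assert {"accuracy_pct_mean", "accuracy_pct_sd"} <= set(report.table.columns)

    def test_classifier_failure_recorded_run_continues(self):
        fm = separable_features()

        class Broken:
            def train(self, *a):
                raise RuntimeError("boom")

            def predict(self, X):  # pragma: no cover
                raise RuntimeError("boom")

        clfs = {"broken": Broken(),
                "ann": make_classifier("ann", seed=3, hidden=[3], max_epoch=20)}
        report = compare_classifiers(fm, clfs, protocol="holdout", seed=3)
        assert "broken" in report.errors and "ann" in report.reports

    def test_unknown_protocol_and_kind(self):
        with pytest.raises(ValueError, match="protocol"):
            compare_classifiers(separable_features(), {}, protocol="loo")
        with pytest.raises(ValueError, match="unknown classifier"):
            make_classifier("svm")
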