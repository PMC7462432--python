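"""High/low adherence classification: labels, splits, elimination, ROC."""

import numpy as np
import pandas as pd
import pytest

from adherenet.adherence_classifier import (
    FeatureTable,
    backward_elimination,
    build_feature_table,
    holdout_split,
    label_binarize,
    loocv_accuracy,
    roc_curve,
    train_and_evaluate,
)
from adherenet.io_formats import AdherenceRecord, RunConfig
from adherenet.stat_inference import RobustNodeSet

import oracles


def _records(homeworks, group="meditation"):
    return [AdherenceRecord(f"p{i}", group, h, 2) for i, h in enumerate(homeworks)]


def _feature_table(X, ids=None, names=None, threshold=0.35):
    n, m = X.shape
    ids = ids or [f"p{i}" for i in range(n)]
    names = names or [f"f{j}" for j in range(m)]
    df = pd.DataFrame(X, index=ids, columns=names)
    prov = tuple((c, "clustering") for c in names)
    return FeatureTable(df, threshold, prov)


def _gaussian_classes(rng, n, sep, m_noise=2):
    """Two Gaussian classes separated by `sep` along one informative feature."""
    y = np.array([1] * (n // 2) + [0] * (n - n // 2))
    X = rng.standard_normal((n, 1 + m_noise))
    X[:, 0] += sep * y
    return X, y


class TestLabelBinarize:
    @pytest.mark.parametrize("homework,expected", [(12, "high"), (10, "low"), (0, "low")])
    def test_strict_cutoff_boundary(self, homework, expected):
        [label] = label_binarize(_records([homework]), cutoff=10)
        assert label.label == expected


class TestHoldoutSplit:
    def test_balanced_cohort_splits_exactly(self, rng):
        X = rng.standard_normal((48, 3))
        table = _feature_table(X)
        labels = label_binarize(_records([15] * 24 + [5] * 24))
        train, y_tr, heldout, y_te = holdout_split(table, labels, 0.25, seed=0)
        assert len(y_te) == 12
        assert sum(1 for l in y_te if l.label == "high") == 6
        assert set(train.participant_ids).isdisjoint(heldout.participant_ids)

    def test_uneven_cohort_close_to_proportional(self, rng):
        X = rng.standard_normal((51, 3))
        table = _feature_table(X)
        labels = label_binarize(_records([15] * 28 + [5] * 23))
        _, _, heldout, y_te = holdout_split(table, labels, 0.25, seed=1)
        assert len(y_te) == 13  # round(0.25 * 51)
        n_high = sum(1 for l in y_te if l.label == "high")
        assert abs(n_high - 0.25 * 28) <= 1

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((20, 2))
        table = _feature_table(X)
        labels = label_binarize(_records([15] * 10 + [5] * 10))
        s1 = holdout_split(table, labels, 0.25, seed=3)
        s2 = holdout_split(table, labels, 0.25, seed=3)
        assert s1[0].participant_ids == s2[0].participant_ids
        assert s1[2].participant_ids == s2[2].participant_ids

    def test_tiny_class_rejected(self, rng):
        X = rng.standard_normal((10, 2))
        table = _feature_table(X)
        labels = label_binarize(_records([15] + [5] * 9))
        with pytest.raises(ValueError, match="< 2 members"):
            holdout_split(table, labels, 0.25, seed=0)


class TestRocCurve:
    def test_perfectly_ordered_scores(self):
        _, _, auc = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_uninformative_constant_scores(self):
        _, _, auc = roc_curve([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
        assert auc == pytest.approx(0.5)

    def test_concordant_pair_example(self):
        _, _, auc = roc_curve([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0])
        assert auc == pytest.approx(0.75)

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.standard_normal(30)
        labels = rng.integers(0, 2, 30)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        fpr, tpr, _ = roc_curve(scores, labels)
        assert fpr[0] == 0 and tpr[0] == 0
        assert fpr[-1] == 1 and tpr[-1] == 1
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_trapezoid_equals_concordance_count(self, rng):
        """Trapezoidal AUC == normalized Mann-Whitney U on random draws."""
        for _ in range(300):
            n = int(rng.integers(4, 25))
            scores = np.round(rng.standard_normal(n), 1)  # force ties sometimes
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            _, _, auc = roc_curve(scores, labels)
            assert auc == pytest.approx(
                oracles.auc_concordance_oracle(scores, labels), abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.9], [1, 1])


class TestBackwardElimination:
    def test_single_feature_returned_unchanged_with_warning(self, rng):
        X = rng.standard_normal((12, 1))
        table = _feature_table(X)
        labels = label_binarize(_records([15] * 6 + [5] * 6))
        with pytest.warns(UserWarning, match="single-feature"):
            reduced, order = backward_elimination(table, labels, seed=0)
        assert list(reduced.values.columns) == ["f0"]
        assert order == []

    def test_duplicated_informative_column_is_pruned(self, rng):
        y = np.array([1] * 10 + [0] * 10)
        info = y + 0.05 * rng.standard_normal(20)
        X = np.column_stack([info, info, rng.standard_normal(20)])
        table = _feature_table(X, names=["dup_a", "dup_b", "noise"])
        labels = label_binarize(_records([15] * 10 + [5] * 10))
        reduced, order = backward_elimination(table, labels, seed=0,
                                              min_features=1, n_estimators=25)
        kept = set(reduced.values.columns)
        assert len({"dup_a", "dup_b"} & kept) <= 1

    def test_all_noise_terminates_at_minimum_feature_count(self, rng):
        X = rng.standard_normal((14, 5))
        table = _feature_table(X)
        labels = label_binarize(_records([15] * 7 + [5] * 7))
        reduced, order = backward_elimination(table, labels, seed=1,
                                              min_features=2, n_estimators=15)
        assert len(reduced.values.columns) >= 2
        assert len(order) == 5 - len(reduced.values.columns)

    def test_informative_feature_survives_pruning(self, rng):
        """A strongly informative feature outlasts pure-noise companions."""
        kept_count = 0
        runs = 8
        for seed in range(runs):
            local = np.random.default_rng(1000 + seed)
            X, y = _gaussian_classes(local, 30, sep=3.0, m_noise=5)
            table = _feature_table(X, names=["signal"] + [f"noise{j}" for j in range(5)])
            labels = label_binarize(_records([15 if v else 5 for v in y]))
            reduced, _ = backward_elimination(table, labels, seed=seed,
                                              min_features=1, n_estimators=25)
            kept_count += "signal" in reduced.values.columns
        assert kept_count >= int(0.9 * runs)


class TestTrainAndEvaluate:
    def test_deterministic_classifiers_have_zero_ci_width(self, rng):
        X, y = _gaussian_classes(rng, 24, sep=2.0)
        table = _feature_table(X)
        labels = label_binarize(_records([15 if v else 5 for v in y]))
        train, y_tr, heldout, y_te = holdout_split(table, labels, 0.25, seed=0)
        # a tree with one fixed seed repeated is deterministic; naive Bayes has
        # no internal randomness at all, so any seed list gives equal scores
        fixed = RunConfig(seeds=(7, 7, 7, 7, 7))
        report = train_and_evaluate(train, y_tr, heldout, y_te, fixed,
                                    classifiers=("decision_tree",))
        tree = report.per_classifier["decision_tree"]
        assert len(set(tree.cv_scores)) == 1 and tree.cv_ci95 == 0.0

        varied = RunConfig()  # five different seeds
        report = train_and_evaluate(train, y_tr, heldout, y_te, varied,
                                    classifiers=("naive_bayes",))
        nb = report.per_classifier["naive_bayes"]
        assert len(set(nb.cv_scores)) == 1 and nb.cv_ci95 == 0.0

    def test_single_class_heldout_leaves_auc_undefined(self, rng):
        X, y = _gaussian_classes(rng, 20, sep=2.0)
        table = _feature_table(X)
        labels = label_binarize(_records([15 if v else 5 for v in y]))
        train, y_tr, heldout, y_te = holdout_split(table, labels, 0.25, seed=0)
        forced = [l for l in y_te]
        from adherenet.adherence_classifier import AdherenceLabel
        forced = [AdherenceLabel(l.participant_id, "high") for l in y_te]
        cfg = RunConfig(seeds=(0,))
        report = train_and_evaluate(train, y_tr, heldout, forced, cfg,
                                    classifiers=("naive_bayes",))
        assert report.per_classifier["naive_bayes"].auc is None

    def test_pooled_summary_covers_all_classifier_seed_scores(self, rng):
        X, y = _gaussian_classes(rng, 24, sep=2.0)
        table = _feature_table(X)
        labels = label_binarize(_records([15 if v else 5 for v in y]))
        train, y_tr, heldout, y_te = holdout_split(table, labels, 0.25, seed=0)
        cfg = RunConfig(seeds=(0, 1))
        report = train_and_evaluate(train, y_tr, heldout, y_te, cfg)
        all_scores = [s for sc in report.per_classifier.values() for s in sc.cv_scores]
        assert len(all_scores) == 4 * 2
        assert report.pooled_cv_mean == pytest.approx(np.mean(all_scores))


class TestAntiLeakage:
    def test_selecting_features_on_all_data_inflates_null_accuracy(self, rng):
        """Under pure-noise features and labels, choosing the most
        label-correlated features on the full data before LOOCV yields
        optimistically biased scores; selecting within each training fold does
        not. The gap demonstrates why selection must stay inside the fold."""
        from sklearn.naive_bayes import GaussianNB
        from sklearn.model_selection import LeaveOneOut

        def top_k(X, y, k):
            r = np.abs([oracles.pearson_oracle(X[:, j], y) for j in range(X.shape[1])])
            return np.argsort(r)[-k:]

        leaked, proper = [], []
        for seed in range(6):
            local = np.random.default_rng(2000 + seed)
            X = local.standard_normal((24, 60))
            y = np.array([1] * 12 + [0] * 12)
            # leaked: feature choice sees every label, including the test fold's
            cols = top_k(X, y, 4)
            leaked.append(loocv_accuracy(GaussianNB(), X[:, cols], y))
            # proper: choice re-made inside each LOOCV training fold
            correct = 0
            for train_idx, test_idx in LeaveOneOut().split(X):
                cols = top_k(X[train_idx], y[train_idx], 4)
                clf = GaussianNB().fit(X[train_idx][:, cols], y[train_idx])
                correct += clf.predict(X[test_idx][:, cols])[0] == y[test_idx][0]
            proper.append(correct / len(y))
        assert np.mean(leaked) > np.mean(proper) + 0.1


def test_build_feature_table_restricts_to_robust_nodes(small_cohort, fast_config):
    from adherenet.graph_metrics import cohort_metric_table
    ts_sets, records, aff = small_cohort
    table = cohort_metric_table(ts_sets, aff, fast_config,
                                global_metrics=(), nodal_metrics=("clustering", "degree"))
    robust = RobustNodeSet("clustering", "all", "homework", 3,
                           {ts_sets[0].roi_labels[0]: 5, ts_sets[0].roi_labels[3]: 4})
    features = build_feature_table(table, [robust], threshold=0.35)
    assert features.values.shape == (len(ts_sets), 2)
    assert features.provenance == ((ts_sets[0].roi_labels[0], "clustering"),
                                   (ts_sets[0].roi_labels[3], "clustering"))
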