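"""Decision-tree induction, pruning, rules, CV and published-tree probes."""

import math

import numpy as np
import pandas as pd
import pytest

import cohgraph as cg
from cohgraph.bands import ALPHA, THETA
from cohgraph.connectivity import ConnectivityMatrix
from cohgraph.tree import Condition, _added_errors, build_tree_from_rules

from published_models import AA_LA_TREE, HA_LA_TREE


def _entropy(labels):
    n = len(labels)
    out = 0.0
    for c in set(labels):
        p = labels.count(c) / n
        out -= p * math.log2(p)
    return out


def _brute_force_best_ratio(X, y, min_leaf):
    """Exhaustive gain-ratio search over every feature and midpoint."""
    n, p = X.shape
    h = _entropy(list(y))
    best = 0.0
    for j in range(p):
        for thr in sorted(set(X[:, j])):
            left = [y[i] for i in range(n) if X[i, j] <= thr]
            right = [y[i] for i in range(n) if X[i, j] > thr]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            gain = h - (len(left) / n * _entropy(left)
                        + len(right) / n * _entropy(right))
            if gain <= 1e-12:
                continue
            split_info = _entropy(["L"] * len(left) + ["R"] * len(right))
            best = max(best, gain / split_info)
    return best


class TestInduction:
    def test_single_feature_toy_split(self):
        X = np.array([[0.2], [0.4], [0.6], [0.8]])
        y = np.array(["A", "A", "B", "B"])
        m = cg.C45TreeClassifier().fit(X, y)
        assert m.tree_.threshold == pytest.approx(0.5)
        assert m.tree_.n_leaves == 2
        assert list(m.predict([[0.1], [0.9]])) == ["A", "B"]

    def test_pure_class_gives_single_leaf(self):
        m = cg.C45TreeClassifier().fit(np.random.rand(6, 3), ["A"] * 6)
        assert m.tree_.is_leaf
        assert m.predict(np.random.rand(2, 3)).tolist() == ["A", "A"]

    def test_constant_features_give_majority_leaf(self):
        X = np.ones((7, 2))
        y = np.array(["A", "A", "A", "A", "B", "B", "B"])
        m = cg.C45TreeClassifier().fit(X, y)
        assert m.tree_.is_leaf
        assert m.predict([[1, 1]])[0] == "A"

    def test_root_gain_ratio_matches_exhaustive_search(self):
        """The chosen root split attains the brute-force maximum gain ratio
        on every random dataset with <= 8 instances and <= 3 features."""
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(60):
            n = int(rng.integers(4, 9))
            p = int(rng.integers(1, 4))
            X = np.round(rng.random((n, p)), 2)
            y = rng.choice(["A", "B"], size=n)
            if len(set(y)) < 2:
                continue
            oracle = _brute_force_best_ratio(X, list(y), min_leaf=1)
            m = cg.C45TreeClassifier(min_leaf=1, prune=False).fit(X, y)
            if oracle == 0.0:
                assert m.tree_.is_leaf
                continue
            node = m.tree_
            assert not node.is_leaf
            j, thr = node.feature, node.threshold
            left = [y[i] for i in range(n) if X[i, j] <= thr]
            right = [y[i] for i in range(n) if X[i, j] > thr]
            gain = _entropy(list(y)) - (
                len(left) / n * _entropy(left) + len(right) / n * _entropy(right))
            ratio = gain / _entropy(["L"] * len(left) + ["R"] * len(right))
            assert ratio == pytest.approx(oracle, abs=1e-10)
            checked += 1
        assert checked >= 30

    def test_planted_electrode_selected_as_root(self):
        cfg = cg.SimConfig(n_subjects_per_class=15, class_labels=("HA", "LA"),
                           planted_electrodes=("T3",), seed=2)
        table, _ = cg.generate_feature_cohort(
            cfg, baseline_sd=0.06, class_offsets={"LA": 0.18, "HA": 0.0})
        m = cg.C45TreeClassifier().fit(table.features, table.classes.to_numpy())
        assert m.root_feature() == "T3"


class TestPruning:
    def test_pruned_tree_never_larger(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            X = rng.random((40, 4))
            y = rng.choice(["A", "B"], size=40)
            pruned = cg.C45TreeClassifier(prune=True).fit(X, y)
            grown = cg.C45TreeClassifier(prune=False).fit(X, y)
            assert pruned.tree_.n_leaves <= grown.tree_.n_leaves

    def test_training_accuracy_at_least_majority(self):
        rng = np.random.default_rng(4)
        X = rng.random((30, 3))
        y = rng.choice(["A", "B"], size=30, p=[0.7, 0.3])
        m = cg.C45TreeClassifier().fit(X, y)
        acc = (m.predict(X) == y).mean()
        majority = max((y == c).mean() for c in set(y))
        assert acc >= majority - 1e-12

    def test_added_errors_monotone_in_confidence(self):
        assert _added_errors(20, 3, 0.25) > _added_errors(20, 3, 0.5)
        assert _added_errors(10, 0, 0.25) > 0


class TestRules:
    def test_rules_partition_and_agree_with_tree(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.random((50, 5)),
                         columns=["C3", "Cz", "T3", "P3", "O1"])
        y = rng.choice(["HA", "LA"], size=50)
        m = cg.C45TreeClassifier().fit(X, y)
        rules = cg.extract_rules(m)
        assert len(rules) == m.tree_.n_leaves
        probes = rng.random((10_000, 5))
        tree_pred = m.predict(probes)
        for x, expect in zip(probes, tree_pred):
            row = dict(zip(X.columns, x))
            matching = [r for r in rules if r.matches(row)]
            assert len(matching) == 1  # partition of the feature space
            assert matching[0].klass == expect

    def test_condition_rendering(self):
        c = Condition("T3", "<=", 0.73)
        assert str(c) == "T3 <= 0.73"
        assert c.holds(0.73) and not c.holds(0.74)


class TestPublishedTreeProbes:
    """Replaying the printed decision logic of the reported models."""

    def test_ha_la_alpha_rules(self):
        m = build_tree_from_rules(HA_LA_TREE, ["HA", "LA"])
        rules = cg.extract_rules(m)
        assert rules.classify({"T3": 0.80, "Cz": 0.60}) == "LA"
        assert rules.classify({"T3": 0.70, "Cz": 0.70}) == "HA"
        assert rules.classify({"T3": 0.70, "Cz": 0.50}) == "LA"
        assert rules.classify({"T3": 0.70, "Cz": 0.90}) == "LA"

    def test_aa_la_theta_rules(self):
        m = build_tree_from_rules(AA_LA_TREE, ["AA", "LA"])
        rules = cg.extract_rules(m)
        assert rules.classify({"P3": 0.50, "Pz": 0.90, "F4": 0.90}) == "AA"
        assert rules.classify({"P3": 0.70, "Pz": 0.70, "F4": 0.10}) == "LA"
        assert rules.classify({"P3": 0.70, "Pz": 0.90, "F4": 0.80}) == "LA"
        assert rules.classify({"P3": 0.70, "Pz": 0.90, "F4": 0.60}) == "AA"


class TestCrossValidation:
    def test_confusion_arithmetic(self):
        cm = cg.ConfusionCounts(tp=3, tn=2, fp=1, fn=0)
        assert cm.accuracy * 100 == pytest.approx(83.33, abs=0.01)

    def test_perfectly_separable_pair_scores_100(self):
        X = np.vstack([np.zeros((12, 2)), np.ones((12, 2))])
        y = np.array(["A"] * 12 + ["B"] * 12)
        for seed in (0, 1, 2):
            res = cg.cross_validate(X, y, folds=4, repeats=2, seed=seed)
            assert res.mean_accuracy_pct == 100.0

    def test_stratified_folds_within_one_instance(self):
        from sklearn.model_selection import RepeatedStratifiedKFold

        y = np.array(["A"] * 15 + ["B"] * 14)
        splitter = RepeatedStratifiedKFold(n_splits=10, n_repeats=2,
                                           random_state=0)
        for _, test_idx in splitter.split(np.zeros((29, 1)), y):
            frac_a = (y[test_idx] == "A").sum()
            expected = 15 * len(test_idx) / 29
            assert abs(frac_a - expected) <= 1.0

    def test_fold_reduction_warns_for_small_classes(self):
        X = np.random.default_rng(0).random((8, 2))
        y = np.array(["A"] * 4 + ["B"] * 4)
        with pytest.warns(UserWarning, match="reducing folds"):
            res = cg.cross_validate(X, y, folds=10, repeats=1, seed=0)
        assert res.folds == 4

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cg.cross_validate(np.zeros((0, 2)), np.array([]))

    def test_confusion_total_covers_all_instances(self):
        rng = np.random.default_rng(6)
        X = rng.random((25, 3))
        y = rng.choice(["A", "B"], size=25)
        res = cg.cross_validate(X, y, folds=5, repeats=3, seed=1)
        assert res.confusion.total == 25 * 3


class TestClassAverageConnectivity:
    def _mat(self, sid, band, pairs):
        W = np.zeros((19, 19))
        for a, b, w in pairs:
            i, j = cg.CHANNELS.index(a), cg.CHANNELS.index(b)
            W[i, j] = W[j, i] = w
        return ConnectivityMatrix(W=W, threshold_value=0.5, band=band,
                                  subject_id=sid)

    def test_single_subject_mean_is_identity(self):
        m = self._mat("s1", ALPHA, [("T3", "Cz", 0.9)])
        avg = cg.class_average_connectivity([m], {"s1": "LA"}, ["T3"])
        assert np.array_equal(avg.mean_matrices[("LA", "alpha")], m.W)

    def test_mean_of_present_and_absent_edge(self):
        m1 = self._mat("s1", ALPHA, [("T3", "Cz", 0.8)])
        m2 = self._mat("s2", ALPHA, [])
        avg = cg.class_average_connectivity(
            [m1, m2], {"s1": "LA", "s2": "LA"}, ["T3"])
        W = avg.mean_matrices[("LA", "alpha")]
        assert W[cg.CHANNELS.index("T3"), cg.CHANNELS.index("Cz")] == pytest.approx(0.4)

    def test_planted_neighborhood_recovered_per_class(self):
        la = [self._mat(f"l{i}", ALPHA, [("T3", "Cz", 0.9), ("T3", "F3", 0.2)])
              for i in range(3)]
        ha = [self._mat(f"h{i}", ALPHA, [("T3", "F3", 0.3)]) for i in range(3)]
        labels = {m.subject_id: ("LA" if m.subject_id[0] == "l" else "HA")
                  for m in la + ha}
        avg = cg.class_average_connectivity(la + ha, labels, ["T3"])
        la_hood = avg.neighborhoods[("LA", "alpha", "T3")]
        assert la_hood[0][0] == "Cz"
        ha_hood = avg.neighborhoods[("HA", "alpha", "T3")]
        assert "Cz" not in [p for p, _ in ha_hood]

    def test_unknown_electrode_rejected(self):
        m = self._mat("s1", THETA, [])
        with pytest.raises(ValueError, match="electrode"):
            cg.class_average_connectivity([m], {"s1": "HA"}, ["XX"])
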