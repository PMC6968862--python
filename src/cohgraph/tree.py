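"""C4.5-style decision trees with rule extraction and repeated stratified CV.

The classifier grows a binary tree top-down, choosing at each node the
(feature, threshold) split with the highest gain ratio; candidate
thresholds are the midpoints between consecutive distinct training
values of each feature. Growth stops when no split has positive
information gain or would leave a child smaller than ``min_leaf``.
Pruning is pessimistic-error pruning: each subtree's training error is
inflated to an upper confidence bound (normal approximation at the
given confidence factor) and the subtree is collapsed to a leaf when
the leaf's bound is no worse. No subtree raising is performed, and the
MDL correction for continuous attributes is off by default.

Every leaf corresponds to one conjunctive rule over electrode
thresholds; the rule set partitions the feature space and reproduces
the tree's predictions exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .connectivity import ConnectivityMatrix
from .montage import CHANNELS

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Tree structure


@dataclass
class TreeNode:
    """A node of the fitted tree; leaves carry a class, internal nodes a split."""

    counts: np.ndarray                       # training class counts at the node
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None           # x[feature] <= threshold
    right: "TreeNode | None" = None          # x[feature] >  threshold

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def klass(self) -> int:
        return int(np.argmax(self.counts))

    @property
    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves + self.right.n_leaves

    def to_dict(self, classes: Sequence, feature_names: Sequence[str]) -> dict:
        if self.is_leaf:
            return {
                "leaf": str(classes[self.klass]),
                "counts": {str(c): int(n) for c, n in zip(classes, self.counts)},
            }
        return {
            "feature": feature_names[self.feature],
            "threshold": float(self.threshold),
            "le": self.left.to_dict(classes, feature_names),
            "gt": self.right.to_dict(classes, feature_names),
        }


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _added_errors(n: float, e: float, cf: float) -> float:
    """Pessimistic extra errors for a node with n instances and e errors.

    Normal-approximation upper confidence bound on the binomial error
    rate at confidence factor ``cf`` (the classic C4.5/J48 estimate,
    with the small-count special cases).
    """
    if n == 0:
        return 0.0
    if e < 1:
        base = n * (1.0 - cf ** (1.0 / n))
        if e == 0:
            return base
        return base + e * (_added_errors(n, 1.0, cf) - base)
    if e + 0.5 >= n:
        return max(n - e, 0.0)
    z = norm.ppf(1.0 - cf)
    f = (e + 0.5) / n
    r = (f + z * z / (2 * n) + z * np.sqrt(f / n - f * f / n + z * z / (4 * n * n))) \
        / (1.0 + z * z / n)
    return r * n - e


# ---------------------------------------------------------------------------
# Estimator


class C45TreeClassifier(BaseEstimator, ClassifierMixin):
    """Gain-ratio decision tree with pessimistic-error pruning.

    Parameters
    ----------
    confidence_factor:
        Confidence factor of the pruning error estimate; smaller values
        prune more aggressively. Default 0.25.
    min_leaf:
        Minimum number of training instances in any leaf. Default 2.
    prune:
        Whether to apply pessimistic-error pruning after growth.
    mdl_penalty:
        Subtract log2(n_candidate_thresholds)/n from each continuous
        split's information gain (the Release-8 correction). Off by
        default.

    Attributes
    ----------
    classes_:
        Sorted class labels.
    tree_:
        Root :class:`TreeNode` of the fitted (possibly pruned) tree.
    feature_names_in_:
        Column names when fitted from a DataFrame.
    """

    def __init__(
        self,
        confidence_factor: float = 0.25,
        min_leaf: int = 2,
        prune: bool = True,
        mdl_penalty: bool = False,
    ):
        self.confidence_factor = confidence_factor
        self.min_leaf = min_leaf
        self.prune = prune
        self.mdl_penalty = mdl_penalty

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if np.isnan(X).any():
            raise ValueError("X contains NaN")
        if X.shape[0] < 1:
            raise ValueError("empty training set")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        self.n_features_in_ = X.shape[1]
        root = self._grow(X, y_enc)
        self.n_leaves_unpruned_ = root.n_leaves
        if self.prune:
            root = self._prune(root, X, y_enc)
        self.tree_ = root
        return self

    def _class_counts(self, y_enc: np.ndarray) -> np.ndarray:
        return np.bincount(y_enc, minlength=len(self.classes_))

    def _best_split(self, X: np.ndarray, y_enc: np.ndarray):
        """Exhaustive gain-ratio search over midpoint thresholds.

        Returns (feature, threshold, gain_ratio) or None. Ties resolve to
        the earlier feature, then the lower threshold.
        """
        n, p = X.shape
        parent = self._class_counts(y_enc)
        h_parent = _entropy(parent)
        k = len(self.classes_)
        best = None  # (gain_ratio, feature, threshold)
        for j in range(p):
            order = np.argsort(X[:, j], kind="stable")
            xs = X[order, j]
            ys = y_enc[order]
            # prefix class counts
            onehot = np.zeros((n, k))
            onehot[np.arange(n), ys] = 1.0
            prefix = np.cumsum(onehot, axis=0)
            distinct_gap = np.flatnonzero(np.diff(xs) > 0)  # split after index i
            n_candidates = distinct_gap.size
            if n_candidates == 0:
                continue
            penalty = np.log2(n_candidates) / n if self.mdl_penalty else 0.0
            for i in distinct_gap:
                n_left = i + 1
                n_right = n - n_left
                if n_left < self.min_leaf or n_right < self.min_leaf:
                    continue
                left = prefix[i]
                right = parent - left
                gain = h_parent - (
                    n_left / n * _entropy(left) + n_right / n * _entropy(right)
                )
                gain -= penalty
                if gain <= 1e-12:
                    continue
                split_info = _entropy(np.array([n_left, n_right]))
                ratio = gain / split_info
                thr = (xs[i] + xs[i + 1]) / 2.0
                if best is None or ratio > best[0] + 1e-12:
                    best = (ratio, j, thr)
        if best is None:
            return None
        return best[1], best[2], best[0]

    def _grow(self, X: np.ndarray, y_enc: np.ndarray) -> TreeNode:
        counts = self._class_counts(y_enc)
        node = TreeNode(counts=counts)
        if _entropy(counts) == 0 or X.shape[0] < 2 * self.min_leaf:
            return node
        found = self._best_split(X, y_enc)
        if found is None:
            return node
        j, thr, _ = found
        mask = X[:, j] <= thr
        node.feature = j
        node.threshold = thr
        node.left = self._grow(X[mask], y_enc[mask])
        node.right = self._grow(X[~mask], y_enc[~mask])
        return node

    def _subtree_estimated_errors(self, node: TreeNode) -> float:
        if node.is_leaf:
            e = node.n - node.counts[node.klass]
            return e + _added_errors(node.n, e, self.confidence_factor)
        return (
            self._subtree_estimated_errors(node.left)
            + self._subtree_estimated_errors(node.right)
        )

    def _prune(self, node: TreeNode, X: np.ndarray, y_enc: np.ndarray) -> TreeNode:
        if node.is_leaf:
            return node
        mask = X[:, node.feature] <= node.threshold
        node.left = self._prune(node.left, X[mask], y_enc[mask])
        node.right = self._prune(node.right, X[~mask], y_enc[~mask])
        e_leaf = node.n - node.counts[node.klass]
        est_leaf = e_leaf + _added_errors(node.n, e_leaf, self.confidence_factor)
        est_tree = self._subtree_estimated_errors(node)
        if est_leaf <= est_tree + 0.1:  # J48's slack before keeping a subtree
            return TreeNode(counts=node.counts)
        return node

    # -- prediction -------------------------------------------------------

    def predict(self, X):
        check_is_fitted(self, "tree_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0], dtype=int)
        for i, x in enumerate(X):
            node = self.tree_
            while not node.is_leaf:
                node = node.left if x[node.feature] <= node.threshold else node.right
            out[i] = node.klass
        return self.classes_[out]

    # -- introspection ----------------------------------------------------

    def feature_names(self) -> list[str]:
        check_is_fitted(self, "tree_")
        if hasattr(self, "feature_names_in_"):
            return [str(n) for n in self.feature_names_in_]
        return [f"x{j}" for j in range(self.n_features_in_)]

    def root_feature(self) -> str | None:
        """Name of the root split feature, or None for a single-leaf tree."""
        check_is_fitted(self, "tree_")
        if self.tree_.is_leaf:
            return None
        return self.feature_names()[self.tree_.feature]

    def to_dict(self) -> dict:
        check_is_fitted(self, "tree_")
        return self.tree_.to_dict(self.classes_, self.feature_names())


# ---------------------------------------------------------------------------
# Rule extraction


@dataclass(frozen=True)
class Condition:
    feature: str
    op: str        # "<=" or ">"
    threshold: float

    def holds(self, value: float) -> bool:
        return value <= self.threshold if self.op == "<=" else value > self.threshold

    def __str__(self) -> str:
        return f"{self.feature} {self.op} {self.threshold:g}"


@dataclass(frozen=True)
class Rule:
    conditions: tuple[Condition, ...]
    klass: str

    def matches(self, x: Mapping[str, float]) -> bool:
        return all(c.holds(float(x[c.feature])) for c in self.conditions)

    def __str__(self) -> str:
        if not self.conditions:
            return f"-> {self.klass}"
        body = " and ".join(f"({c})" for c in self.conditions)
        return f"{body} -> {self.klass}"


@dataclass
class RuleSet:
    rules: tuple[Rule, ...]

    def classify(self, x: Mapping[str, float]) -> str:
        for rule in self.rules:
            if rule.matches(x):
                return rule.klass
        raise ValueError("rule set does not cover the input (should be impossible)")

    def __iter__(self):
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)

    def __str__(self) -> str:
        return "\n".join(str(r) for r in self.rules)


def extract_rules(model: C45TreeClassifier) -> RuleSet:
    """One conjunctive rule per leaf, conditions ordered root to leaf."""
    check_is_fitted(model, "tree_")
    names = model.feature_names()
    rules: list[Rule] = []

    def walk(node: TreeNode, conds: tuple[Condition, ...]):
        if node.is_leaf:
            rules.append(Rule(conds, str(model.classes_[node.klass])))
            return
        name = names[node.feature]
        walk(node.left, conds + (Condition(name, "<=", node.threshold),))
        walk(node.right, conds + (Condition(name, ">", node.threshold),))

    walk(model.tree_, ())
    return RuleSet(tuple(rules))


def build_tree_from_rules(
    splits: dict, classes: Sequence[str]
) -> C45TreeClassifier:
    """Construct a fitted classifier from an explicit nested split spec.

    ``splits`` is a nested dict: internal nodes are
    ``{"feature": name, "threshold": t, "le": ..., "gt": ...}`` and
    leaves are ``{"leaf": class_name}``. Useful for encoding published
    trees and replaying their decision logic.
    """
    classes = np.asarray(sorted(classes))
    cls_index = {c: i for i, c in enumerate(classes)}
    feat_names: list[str] = []

    def collect(d: dict):
        if "leaf" in d:
            return
        if d["feature"] not in feat_names:
            feat_names.append(d["feature"])
        collect(d["le"])
        collect(d["gt"])

    collect(splits)

    def build(d: dict) -> TreeNode:
        counts = np.zeros(len(classes))
        if "leaf" in d:
            counts[cls_index[d["leaf"]]] = 1
            return TreeNode(counts=counts)
        node = TreeNode(
            counts=counts,
            feature=feat_names.index(d["feature"]),
            threshold=float(d["threshold"]),
            left=build(d["le"]),
            right=build(d["gt"]),
        )
        node.counts = node.left.counts + node.right.counts
        return node

    model = C45TreeClassifier()
    model.classes_ = classes
    model.n_features_in_ = len(feat_names)
    model.feature_names_in_ = np.asarray(feat_names, dtype=object)
    model.tree_ = build(splits)
    return model


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        """Fraction of correct predictions: (TP + TN) / total."""
        if self.total == 0:
            return 0.0
        return (self.tp + self.tn) / self.total


@dataclass
class CVResult:
    fold_accuracies: np.ndarray    # (repeats, folds)
    confusion: ConfusionCounts
    seed: int
    folds: int
    repeats: int
    dataset_name: str = ""

    @property
    def mean_accuracy_pct(self) -> float:
        """Mean fold accuracy as a percentage, rounded to two decimals."""
        return round(float(self.fold_accuracies.mean()) * 100.0, 2)


def cross_validate(
    X,
    y,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    dataset_name: str = "",
    **tree_params,
) -> CVResult:
    """Repeated stratified k-fold evaluation of the C4.5-style tree.

    Folds are stratified and re-shuffled every repeat from ``seed``.
    The positive class for the confusion counts is the first (sorted)
    class label. If the smallest class has fewer members than ``folds``,
    the fold count is reduced to it with a warning.
    """
    if isinstance(X, pd.DataFrame):
        feature_frame = X
    else:
        feature_frame = pd.DataFrame(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("empty dataset")
    classes, counts = np.unique(y, return_counts=True)
    min_class = int(counts.min())
    if min_class < folds:
        warnings.warn(
            f"{dataset_name or 'dataset'}: smallest class has {min_class} members; "
            f"reducing folds from {folds} to {max(2, min_class)}"
        )
        folds = max(2, min_class)

    splitter = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=repeats, random_state=seed
    )
    pos = classes[0]
    acc = np.empty(folds * repeats)
    cm = ConfusionCounts()
    Xn = feature_frame.to_numpy(dtype=float)
    for f, (tr, te) in enumerate(splitter.split(Xn, y)):
        model = C45TreeClassifier(**tree_params).fit(feature_frame.iloc[tr], y[tr])
        pred = model.predict(feature_frame.iloc[te])
        truth = y[te]
        cm.tp += int(((pred == pos) & (truth == pos)).sum())
        cm.tn += int(((pred != pos) & (truth != pos)).sum())
        cm.fp += int(((pred == pos) & (truth != pos)).sum())
        cm.fn += int(((pred != pos) & (truth == pos)).sum())
        acc[f] = float((pred == truth).mean())
    return CVResult(
        fold_accuracies=acc.reshape(repeats, folds),
        confusion=cm,
        seed=seed,
        folds=folds,
        repeats=repeats,
        dataset_name=dataset_name,
    )


# ---------------------------------------------------------------------------
# Class-average connectivity neighborhoods


@dataclass
class ClassAverageConnectivity:
    """Mean connectivity per (class, band) with electrode neighborhoods."""

    mean_matrices: dict[tuple[str, str], np.ndarray]   # (class, band) -> 19x19
    neighborhoods: dict[tuple[str, str, str], list[tuple[str, float]]]
    # (class, band, electrode) -> [(partner, mean weight), ...] sorted desc


def class_average_connectivity(
    matrices: Sequence[ConnectivityMatrix],
    labels: Mapping[str, str],
    electrodes: Sequence[str],
) -> ClassAverageConnectivity:
    """Average connectivity matrices by (class, band); list each selected
    electrode's nonzero mean-weight partners, strongest first."""
    for e in electrodes:
        if e not in CHANNELS:
            raise ValueError(f"unknown electrode label {e!r}")
    groups: dict[tuple[str, str], list[np.ndarray]] = {}
    for m in matrices:
        key = (labels[m.subject_id], m.band.name)
        groups.setdefault(key, []).append(m.W)
    means = {k: np.mean(v, axis=0) for k, v in groups.items()}
    hoods: dict[tuple[str, str, str], list[tuple[str, float]]] = {}
    for (cls, band), W in means.items():
        for e in electrodes:
            i = CHANNELS.index(e)
            partners = [
                (CHANNELS[j], float(W[i, j]))
                for j in np.argsort(-W[i])
                if W[i, j] > 0 and j != i
            ]
            hoods[(cls, band, e)] = partners
    return ClassAverageConnectivity(mean_matrices=means, neighborhoods=hoods)
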