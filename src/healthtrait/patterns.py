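"""Tree-based pattern mining over the binned health score.

The continuous 0-100 score is binned into four classes; a bagged ensemble
of entropy (information-gain) decision trees predicts the class from
categorical covariates; variable importance is out-of-bag permutation
Mean Decrease Accuracy (MDA); and interpretable patterns are root-to-leaf
paths of many shallow trees, filtered at a minimum rule accuracy
(confidence) of 40% - well above the 25% accuracy of a random four-class
classifier - and summarised as the five most accurate patterns per class.

Individual trees are scikit-learn ``DecisionTreeClassifier`` instances
(criterion="entropy"); bagging, out-of-bag evaluation, permutation
importance and path extraction are implemented here so that OOB masks and
rule accuracies are fully controlled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "PatternRule",
    "bin_health",
    "grow_tree",
    "BaggedForest",
    "bagged_forest",
    "cv_accuracy",
    "mda_importance",
    "extract_patterns",
    "top_patterns",
]


def bin_health(score) -> np.ndarray:
    """Four-class binning of the 0-100 health score.

    Cutpoints: (-inf, 20] -> 1, (20, 40] -> 2, (40, 60] -> 3, (60, inf) -> 4.
    Boundaries are closed on the right, so 20 -> 1 and 20.01 -> 2.
    """
    s = np.asarray(score, dtype=float)
    out = np.full(s.shape, 4, dtype=int)
    out[s <= 60] = 3
    out[s <= 40] = 2
    out[s <= 20] = 1
    return out if out.ndim else int(out)


def grow_tree(X, y, max_depth=None, min_leaf: int = 1,
              feature_subset: str | int | None = None, seed: int = 0) -> DecisionTreeClassifier:
    """Entropy-based (information gain) decision tree.

    Splits maximise information gain; growth stops at ``max_depth``,
    ``min_leaf`` or zero gain.  ``feature_subset`` follows scikit-learn's
    ``max_features`` convention ("sqrt", an int, or None for all).
    """
    X = np.asarray(X)
    if X.size == 0:
        raise ValueError("empty feature matrix")
    tree = DecisionTreeClassifier(
        criterion="entropy",
        max_depth=max_depth,
        min_samples_leaf=min_leaf,
        max_features=feature_subset,
        random_state=int(seed),
    )
    return tree.fit(X, y)


@dataclass
class BaggedForest:
    trees: list
    oob_masks: list          # boolean out-of-bag row masks per tree
    classes: np.ndarray
    feature_names: list

    def predict(self, X) -> np.ndarray:
        votes = np.stack([t.predict(np.asarray(X)) for t in self.trees])
        out = np.empty(votes.shape[1], dtype=votes.dtype)
        for j in range(votes.shape[1]):
            vals, counts = np.unique(votes[:, j], return_counts=True)
            out[j] = vals[np.argmax(counts)]  # ties -> lowest class
        return out

    def oob_predict(self, X, permute_col: int | None = None, rng=None) -> np.ndarray:
        """Majority vote over trees for which each row is out-of-bag.

        ``permute_col`` permutes one feature column (per tree, with the
        supplied rng) before predicting - the MDA primitive.
        Rows never out-of-bag get class -1 (excluded from accuracy).
        """
        X = np.asarray(X)
        n = X.shape[0]
        k = self.classes.size
        counts = np.zeros((n, k), dtype=int)
        for tree, oob in zip(self.trees, self.oob_masks):
            if not oob.any():
                continue
            Xo = X[oob]
            if permute_col is not None:
                Xo = Xo.copy()
                Xo[:, permute_col] = rng.permutation(Xo[:, permute_col])
            pred = tree.predict(Xo)
            pred_idx = np.searchsorted(self.classes, pred)
            np.add.at(counts, (np.flatnonzero(oob), pred_idx), 1)
        out = np.full(n, -1, dtype=int)
        voted = counts.sum(axis=1) > 0
        out[voted] = self.classes[np.argmax(counts[voted], axis=1)]
        return out

    def oob_accuracy(self, X, y, permute_col: int | None = None, rng=None) -> float:
        pred = self.oob_predict(X, permute_col=permute_col, rng=rng)
        ok = pred >= 0
        return float(np.mean(pred[ok] == np.asarray(y)[ok]))


def bagged_forest(X, y, n_trees: int = 500, mtry=None, seed: int = 0,
                  max_depth=None, min_leaf: int = 1,
                  bootstrap: bool = True, feature_names=None) -> BaggedForest:
    """Bootstrap-aggregated entropy trees with per-split feature subsets.

    ``mtry`` defaults to ceil(sqrt(p)).  ``bootstrap=False`` trains every
    tree on the full sample (test hook: a 1-tree forest then equals a
    single tree).  Out-of-bag masks are retained for OOB evaluation.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    n, p = X.shape
    if mtry is None:
        mtry = int(np.ceil(np.sqrt(p)))
    rng = np.random.default_rng(seed)
    trees, oob_masks = [], []
    for t in range(n_trees):
        if bootstrap:
            idx = rng.integers(0, n, size=n)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
        else:
            idx = np.arange(n)
            oob = np.zeros(n, dtype=bool)
        tree = grow_tree(
            X[idx], y[idx], max_depth=max_depth, min_leaf=min_leaf,
            feature_subset=mtry, seed=int(rng.integers(2**31 - 1)),
        )
        trees.append(tree)
        oob_masks.append(oob)
    names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(p)]
    return BaggedForest(trees=trees, oob_masks=oob_masks,
                        classes=np.unique(y), feature_names=names)


def cv_accuracy(builder, X, y, k: int = 10, seed: int = 0) -> float:
    """Mean held-out accuracy under seeded stratified k-fold CV.

    ``builder(X_train, y_train)`` must return an object with ``predict``.
    If some class has fewer than ``k`` members (e.g. leave-one-out),
    plain K-fold is used instead.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    min_class = np.bincount(np.unique(y, return_inverse=True)[1]).min()
    if min_class < k:
        skf = KFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(X, y):
        model = builder(X[train], y[train])
        accs.append(float(np.mean(model.predict(X[test]) == y[test])))
    return float(np.mean(accs))


def mda_importance(forest: BaggedForest, X, y, n_perm: int = 10, seed: int = 0) -> dict[str, float]:
    """Permutation Mean Decrease Accuracy, in accuracy points (x100).

    For each feature: baseline OOB accuracy minus the mean OOB accuracy
    with that feature's column permuted, averaged over ``n_perm``
    permutations.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    baseline = forest.oob_accuracy(X, y)
    out = {}
    for j, name in enumerate(forest.feature_names):
        drops = [baseline - forest.oob_accuracy(X, y, permute_col=j, rng=rng)
                 for _ in range(n_perm)]
        out[name] = 100.0 * float(np.mean(drops))
    return out


@dataclass
class PatternRule:
    """A root-to-leaf path read as a conjunction of conditions."""

    conditions: list          # (feature_name, "<=" or ">", threshold)
    predicted_class: int
    support: int              # rows matched on the evaluation sample
    accuracy: float           # fraction of matched rows in the predicted class

    def matches(self, X, feature_index: dict[str, int]) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        mask = np.ones(X.shape[0], dtype=bool)
        for name, op, thr in self.conditions:
            col = X[:, feature_index[name]]
            mask &= (col <= thr) if op == "<=" else (col > thr)
        return mask

    def describe(self) -> str:
        if not self.conditions:
            cond = "(always)"
        else:
            cond = " AND ".join(f"{n} {op} {t:g}" for n, op, t in self.conditions)
        return f"IF {cond} THEN class {self.predicted_class} " \
               f"(support {self.support}, accuracy {self.accuracy:.2f})"


def _tree_paths(tree: DecisionTreeClassifier, feature_names):
    """Enumerate (conditions, predicted_class) for every leaf."""
    t = tree.tree_
    paths = []

    def walk(node, conds):
        if t.children_left[node] == -1:
            counts = t.value[node][0]
            best = np.flatnonzero(counts == counts.max()).min()  # ties -> lowest
            paths.append((list(conds), tree.classes_[best]))
            return
        f = feature_names[t.feature[node]]
        thr = float(t.threshold[node])
        walk(t.children_left[node], conds + [(f, "<=", thr)])
        walk(t.children_right[node], conds + [(f, ">", thr)])

    walk(0, [])
    return paths


def extract_patterns(X, y, feature_names, n_trees: int = 100, min_accuracy: float = 0.40,
                     seed: int = 0, max_depth: int = 5, min_leaf: int = 20,
                     mtry=None) -> list[PatternRule]:
    """Mine classification patterns from an ensemble of seeded trees.

    Each of ``n_trees`` trees is grown on a bootstrap sample with random
    per-split feature subsets; every root-to-leaf path becomes a candidate
    rule whose accuracy (confidence for its predicted class) is evaluated
    on the full sample; rules below ``min_accuracy`` are discarded.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if mtry is None:
        mtry = int(np.ceil(np.sqrt(p)))
    rng = np.random.default_rng(seed)
    feature_index = {f: j for j, f in enumerate(feature_names)}
    rules: list[PatternRule] = []
    seen: set = set()
    for t in range(n_trees):
        idx = rng.integers(0, n, size=n)
        tree = grow_tree(X[idx], y[idx], max_depth=max_depth, min_leaf=min_leaf,
                         feature_subset=mtry, seed=int(rng.integers(2**31 - 1)))
        for conds, cls in _tree_paths(tree, feature_names):
            key = (tuple(conds), cls)
            if key in seen:
                continue
            seen.add(key)
            rule = PatternRule(conditions=conds, predicted_class=int(cls),
                               support=0, accuracy=0.0)
            mask = rule.matches(X, feature_index)
            if not mask.any():
                continue
            rule.support = int(mask.sum())
            rule.accuracy = float(np.mean(y[mask] == cls))
            if rule.accuracy >= min_accuracy:
                rules.append(rule)
    return rules


def top_patterns(rules: list[PatternRule], per_class: int = 5
                 ) -> tuple[list[PatternRule], dict[str, int]]:
    """Most accurate patterns per class plus factor occurrence counts.

    Sorting: accuracy desc, then larger support, then fewer conditions.
    The occurrence table counts, per factor, the selected rules whose
    condition list mentions it (each rule counted once).
    """
    selected: list[PatternRule] = []
    for cls in sorted({r.predicted_class for r in rules}):
        pool = [r for r in rules if r.predicted_class == cls]
        pool.sort(key=lambda r: (-r.accuracy, -r.support, len(r.conditions)))
        selected.extend(pool[:per_class])
    counts: dict[str, int] = {}
    for r in selected:
        for name in {c[0] for c in r.conditions}:
            counts[name] = counts.get(name, 0) + 1
    return selected, dict(sorted(counts.items(), key=lambda kv: -kv[1]))
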