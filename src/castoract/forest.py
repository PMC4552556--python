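"""A from-scratch ensemble of randomized decision trees (random forest).

Each of ``n_trees`` CART-style trees is grown on a bootstrap sample of the
training set; at every node ``mtry`` candidate features are drawn uniformly
without replacement and the (feature, midpoint threshold) split minimising
the weighted Gini impurity is taken. Trees are grown to purity (minimum leaf
size 1, no pruning). The ensemble keeps full out-of-bag (OOB) bookkeeping,
which powers the OOB error estimate, permutation variable importance (mean
decrease in OOB accuracy), logit-scale partial dependence, the proximity
matrix (fraction of trees in which two samples share a terminal node) and
proximity-based class prototypes.

Determinism is defined locally: split ties break to the lowest feature index
then the lowest threshold, and all randomness flows from ``random_state``
through per-tree seed streams, so identical (data, seed) give identical
forests, predictions and importances.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "BehaviourForest",
    "train_forest",
    "predict",
    "oob_error",
    "permutation_importance",
    "partial_dependence",
    "proximity",
    "class_prototypes",
]


@dataclass
class _Tree:
    """Array-packed binary decision tree.

    ``feature[i] >= 0`` marks an internal node (go left iff
    ``x[feature[i]] <= threshold[i]``); ``feature[i] == -1`` a leaf whose
    class is ``leaf_class[i]``. ``n_node_samples`` counts bootstrap samples
    per node (every leaf holds at least one).
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_class: np.ndarray
    n_node_samples: np.ndarray
    bootstrap: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Terminal-node id for every row of X (vectorised level traversal)."""
        node = np.zeros(len(X), dtype=np.intp)
        while True:
            f = self.feature[node]
            live = f >= 0
            if not live.any():
                return node
            idx = np.flatnonzero(live)
            nd = node[idx]
            go_left = X[idx, f[idx]] <= self.threshold[nd]
            node[idx] = np.where(go_left, self.left[nd], self.right[nd])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.leaf_class[self.apply(X)]

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "leaf_class": self.leaf_class.tolist(),
            "n_node_samples": self.n_node_samples.tolist(),
            "bootstrap": self.bootstrap.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_Tree":
        return cls(
            feature=np.asarray(d["feature"], dtype=np.intp),
            threshold=np.asarray(d["threshold"], dtype=float),
            left=np.asarray(d["left"], dtype=np.intp),
            right=np.asarray(d["right"], dtype=np.intp),
            leaf_class=np.asarray(d["leaf_class"], dtype=np.intp),
            n_node_samples=np.asarray(d["n_node_samples"], dtype=np.intp),
            bootstrap=np.asarray(d["bootstrap"], dtype=np.intp),
        )


def _best_split_for_feature(
    values: np.ndarray, y: np.ndarray, n_classes: int
) -> Optional[tuple[float, float]]:
    """(impurity score, threshold) of the best midpoint split on one feature.

    The score is m * weighted Gini = sum_side (m_side - sum_c count_c^2 /
    m_side); lower is better. Returns None when the feature is constant
    within the node. Among tied thresholds the lowest wins.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    boundaries = np.flatnonzero(v[1:] != v[:-1])
    if boundaries.size == 0:
        return None
    ys = y[order]
    m = len(ys)
    onehot = np.zeros((m, n_classes))
    onehot[np.arange(m), ys] = 1.0
    cum = np.cumsum(onehot, axis=0)
    n_left = (boundaries + 1).astype(float)
    n_right = m - n_left
    left_counts = cum[boundaries]
    right_counts = cum[-1] - left_counts
    score = (
        n_left
        - (left_counts**2).sum(axis=1) / n_left
        + n_right
        - (right_counts**2).sum(axis=1) / n_right
    )
    b = int(np.argmin(score))  # first minimum -> lowest threshold
    thr = 0.5 * (v[boundaries[b]] + v[boundaries[b] + 1])
    return float(score[b]), float(thr)


def _grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    mtry: int,
    rng: np.random.Generator,
) -> _Tree:
    n, d = X.shape
    bootstrap = rng.integers(0, n, size=n)
    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    leaf_class: list[int] = []
    n_node: list[int] = []

    def new_node() -> int:
        feature.append(-1)
        threshold.append(np.nan)
        left.append(-1)
        right.append(-1)
        leaf_class.append(-1)
        n_node.append(0)
        return len(feature) - 1

    root = new_node()
    stack: list[tuple[int, np.ndarray]] = [(root, bootstrap)]
    while stack:
        node, idx = stack.pop()
        yn = y[idx]
        n_node[node] = len(idx)
        counts = np.bincount(yn, minlength=n_classes)
        if counts.max() == len(yn):  # pure
            leaf_class[node] = int(np.argmax(counts))
            continue
        Xn = X[idx]
        cand = np.sort(rng.choice(d, size=mtry, replace=False))
        best: Optional[tuple[float, float, int]] = None  # score, thr, feat
        for j in cand:
            res = _best_split_for_feature(Xn[:, j], yn, n_classes)
            if res is None:
                continue
            score, thr = res
            if best is None or score < best[0] - 1e-12:
                best = (score, thr, int(j))
        if best is None:
            # the drawn features are constant here; fall back to the rest so
            # the tree can still grow to purity (identical duplicated rows
            # with different labels remain as impure majority leaves)
            for j in range(d):
                if j in cand:
                    continue
                res = _best_split_for_feature(Xn[:, j], yn, n_classes)
                if res is None:
                    continue
                score, thr = res
                if best is None or score < best[0] - 1e-12:
                    best = (score, thr, int(j))
        if best is None:
            leaf_class[node] = int(np.argmax(counts))
            continue
        _, thr, j = best
        go_left = Xn[:, j] <= thr
        feature[node] = j
        threshold[node] = thr
        nl, nr = new_node(), new_node()
        left[node], right[node] = nl, nr
        stack.append((nl, idx[go_left]))
        stack.append((nr, idx[~go_left]))

    return _Tree(
        feature=np.array(feature, dtype=np.intp),
        threshold=np.array(threshold, dtype=float),
        left=np.array(left, dtype=np.intp),
        right=np.array(right, dtype=np.intp),
        leaf_class=np.array(leaf_class, dtype=np.intp),
        n_node_samples=np.array(n_node, dtype=np.intp),
        bootstrap=bootstrap,
    )


class BehaviourForest(BaseEstimator, ClassifierMixin):
    """Random forest classifier with OOB bookkeeping.

    Parameters
    ----------
    n_trees : int, default 500
        Number of trees in the ensemble.
    mtry : int, default 2
        Number of candidate features drawn (without replacement) per node.
    random_state : int or None
        Seed for the per-tree bootstrap/feature streams.

    Attributes (after ``fit``)
    --------------------------
    classes_ : ndarray of class labels, sorted.
    trees_ : list of fitted trees.
    oob_error_ : float
        Fraction of training samples misclassified by the trees not
        containing them in-bag.
    oob_votes_ : ndarray (n_samples, n_classes)
        OOB vote counts per training sample.
    feature_names_in_ : ndarray of str, when fitted on a DataFrame.
    """

    def __init__(
        self,
        n_trees: int = 500,
        mtry: int = 2,
        random_state: Optional[int] = None,
    ):
        self.n_trees = n_trees
        self.mtry = mtry
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------
    def _validate_X(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if hasattr(self, "n_features_in_") and X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; the forest was trained on "
                f"{self.n_features_in_}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y) -> "BehaviourForest":
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or not np.all(np.isfinite(X)):
            raise ValueError("X must be a finite 2-d array")
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y lengths differ")
        if len(X) < 10:
            raise ValueError("need at least 10 training samples")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        n, d = X.shape
        if not 1 <= self.mtry <= d:
            raise ValueError(f"mtry must be in [1, {d}]")
        if all(np.unique(X[:, j]).size == 1 for j in range(d)):
            warnings.warn(
                "all features are constant; trees degenerate to single leaves",
                stacklevel=2,
            )
        self.n_features_in_ = d
        ss = np.random.SeedSequence(self.random_state)
        self.trees_ = [
            _grow_tree(X, y_enc, len(self.classes_), self.mtry, np.random.default_rng(child))
            for child in ss.spawn(self.n_trees)
        ]
        self._fit_X = X
        self._fit_y = y_enc

        K = len(self.classes_)
        votes = np.zeros((n, K))
        for tree in self.trees_:
            oob = np.flatnonzero(np.bincount(tree.bootstrap, minlength=n) == 0)
            if oob.size:
                pred = tree.predict(X[oob])
                votes[oob, pred] += 1.0
        self.oob_votes_ = votes
        covered = votes.sum(axis=1) > 0
        if not covered.all():
            warnings.warn(
                f"{int((~covered).sum())} training samples were never "
                "out-of-bag and are excluded from the OOB error",
                stacklevel=2,
            )
        self.oob_error_ = float(
            (votes[covered].argmax(axis=1) != y_enc[covered]).mean()
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-class vote fractions (summing to 1 for every sample)."""
        check_is_fitted(self, "trees_")
        X = self._validate_X(X)
        votes = np.zeros((len(X), len(self.classes_)))
        for tree in self.trees_:
            votes[np.arange(len(X)), tree.predict(X)] += 1.0
        return votes / self.n_trees

    def predict(self, X) -> np.ndarray:
        """Majority-vote labels (ties break to the first label in sorted order)."""
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def apply(self, X) -> np.ndarray:
        """(n_samples, n_trees) terminal-node ids."""
        check_is_fitted(self, "trees_")
        X = self._validate_X(X)
        return np.column_stack([tree.apply(X) for tree in self.trees_])

    # -- forest statistics ----------------------------------------------
    def oob_error(self) -> float:
        check_is_fitted(self, "oob_error_")
        return self.oob_error_

    def permutation_importance(self, random_state: Optional[int] = None) -> pd.Series:
        """Permutation variable importance: mean decrease in OOB accuracy.

        For each tree and feature, the feature's values are permuted within
        the tree's OOB set and the drop in that tree's OOB accuracy recorded;
        the per-feature average over trees is reported in percentage points
        (unscaled).
        """
        check_is_fitted(self, "trees_")
        X, y = self._fit_X, self._fit_y
        n, d = X.shape
        rng = np.random.default_rng(
            self.random_state if random_state is None else random_state
        )
        drops = np.zeros(d)
        n_used = 0
        for tree in self.trees_:
            oob = np.flatnonzero(np.bincount(tree.bootstrap, minlength=n) == 0)
            if oob.size == 0:
                continue
            n_used += 1
            Xo, yo = X[oob], y[oob]
            base = (tree.predict(Xo) == yo).mean()
            for j in range(d):
                perm = rng.permutation(len(oob))
                Xp = Xo.copy()
                Xp[:, j] = Xo[perm, j]
                drops[j] += base - (tree.predict(Xp) == yo).mean()
        drops = drops / max(n_used, 1) * 100.0
        index = (
            list(self.feature_names_in_)
            if hasattr(self, "feature_names_in_")
            else [f"x{j}" for j in range(d)]
        )
        return pd.Series(drops, index=index, name="mean_decrease_accuracy_pct")

    def partial_dependence(
        self,
        feature: Union[int, str],
        target_class,
        grid: Optional[np.ndarray] = None,
        X: Optional[np.ndarray] = None,
        n_grid: int = 50,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Centred logit-scale partial dependence of one class on one feature.

        f(x) = mean_i [ log v_c(x; x_i) - (1/K) sum_l log v_l(x; x_i) ] with
        vote fractions floored at 1/(2 n_trees) before the logarithms; the
        curve is centred to zero weighted mean over the empirical feature
        distribution (each grid point weighted by the data mass nearest it).
        Returns (grid, values).
        """
        check_is_fitted(self, "trees_")
        j = self._feature_index(feature)
        Xd = self._fit_X if X is None else self._validate_X(X)
        c = int(np.flatnonzero(self.classes_ == target_class)[0]) if (
            target_class in self.classes_
        ) else -1
        if c < 0:
            raise ValueError(f"unknown class {target_class!r}")
        col = Xd[:, j]
        if grid is None:
            grid = np.linspace(col.min(), col.max(), n_grid)
        else:
            grid = np.asarray(grid, dtype=float)
            if grid.size == 0:
                raise ValueError("empty grid")
        floor = 1.0 / (2.0 * self.n_trees)
        values = np.empty(len(grid))
        Xg = Xd.copy()
        for k, x in enumerate(grid):
            Xg[:, j] = x
            v = np.clip(self.predict_proba(Xg), floor, None)
            logv = np.log(v)
            values[k] = float((logv[:, c] - logv.mean(axis=1)).mean())
        # empirical-density weights: data mass in the Voronoi cell of each
        # grid point (decile-style weighting of the centring mean)
        mids = 0.5 * (grid[1:] + grid[:-1])
        cell = np.searchsorted(mids, col)
        w = np.bincount(cell, minlength=len(grid)).astype(float)
        w /= w.sum()
        return grid, values - float((values * w).sum())

    def proximity(self, X=None) -> np.ndarray:
        """Pairwise proximity: fraction of trees sharing a terminal node."""
        check_is_fitted(self, "trees_")
        Xd = self._fit_X if X is None else self._validate_X(X)
        n = len(Xd)
        prox = np.zeros((n, n))
        for tree in self.trees_:
            leaves = tree.apply(Xd)
            prox += leaves[:, None] == leaves[None, :]
        return prox / self.n_trees

    def class_prototypes(self, n_nbr: int = 20) -> pd.DataFrame:
        """Per-class prototype feature vectors from proximity neighbourhoods.

        For each class, the member whose ``n_nbr`` proximity-nearest
        neighbours contain the most same-class samples is located; the
        prototype is the per-feature median over the member and those
        same-class neighbours.
        """
        check_is_fitted(self, "trees_")
        X, y = self._fit_X, self._fit_y
        prox = self.proximity()
        rows = {}
        for ci, cls in enumerate(self.classes_):
            members = np.flatnonzero(y == ci)
            k = n_nbr
            if k >= len(members):
                k = max(len(members) - 1, 1)
                warnings.warn(
                    f"class {cls!r} has only {len(members)} members; "
                    f"using n_nbr={k}",
                    stacklevel=2,
                )
            best_i, best_count, best_nbrs = -1, -1, None
            for i in members:
                order = np.argsort(-prox[i])
                order = order[order != i][:k]
                count = int((y[order] == ci).sum())
                if count > best_count:
                    best_i, best_count = int(i), count
                    best_nbrs = order[y[order] == ci]
            pool = np.concatenate([[best_i], best_nbrs])
            rows[cls] = np.median(X[pool], axis=0)
        cols = (
            list(self.feature_names_in_)
            if hasattr(self, "feature_names_in_")
            else [f"x{j}" for j in range(X.shape[1])]
        )
        return pd.DataFrame.from_dict(rows, orient="index", columns=cols)

    # -- (de)serialisation ----------------------------------------------
    def to_json(self) -> str:
        """Serialise the fitted forest (trees as flat arrays) to JSON."""
        check_is_fitted(self, "trees_")
        payload = {
            "format": "castoract-forest",
            "version": 1,
            "params": self.get_params(),
            "classes": self.classes_.tolist(),
            "feature_names": (
                list(self.feature_names_in_)
                if hasattr(self, "feature_names_in_")
                else None
            ),
            "trees": [t.to_dict() for t in self.trees_],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str, X=None, y=None) -> "BehaviourForest":
        """Rebuild a forest from :meth:`to_json` output.

        Passing the original (X, y) restores the OOB statistics as well.
        """
        d = json.loads(text)
        if d.get("format") != "castoract-forest":
            raise ValueError("not a serialised forest")
        model = cls(**d["params"])
        model.classes_ = np.asarray(d["classes"])
        model.trees_ = [_Tree.from_dict(t) for t in d["trees"]]
        model.n_features_in_ = (
            max(max(t.feature.max() for t in model.trees_) + 1, 1)
        )
        if d.get("feature_names") is not None:
            model.feature_names_in_ = np.asarray(d["feature_names"], dtype=object)
            model.n_features_in_ = len(d["feature_names"])
        if X is not None and y is not None:
            X = np.asarray(X.to_numpy() if isinstance(X, pd.DataFrame) else X, dtype=float)
            model.n_features_in_ = X.shape[1]
            _, y_enc = np.unique(y, return_inverse=True)
            model._fit_X, model._fit_y = X, y_enc
            n, K = len(X), len(model.classes_)
            votes = np.zeros((n, K))
            for tree in model.trees_:
                oob = np.flatnonzero(np.bincount(tree.bootstrap, minlength=n) == 0)
                if oob.size:
                    votes[oob, tree.predict(X[oob])] += 1.0
            model.oob_votes_ = votes
            covered = votes.sum(axis=1) > 0
            model.oob_error_ = float(
                (votes[covered].argmax(axis=1) != y_enc[covered]).mean()
            )
        return model

    def _feature_index(self, feature: Union[int, str]) -> int:
        if isinstance(feature, str):
            if not hasattr(self, "feature_names_in_"):
                raise ValueError("forest was not fitted with feature names")
            hits = np.flatnonzero(self.feature_names_in_ == feature)
            if hits.size == 0:
                raise ValueError(f"unknown feature {feature!r}")
            return int(hits[0])
        return int(feature)


# -- functional wrappers over the estimator -------------------------------

def train_forest(
    features, labels, n_trees: int = 500, mtry: int = 2, seed: Optional[int] = None
) -> BehaviourForest:
    """Fit a :class:`BehaviourForest` on a feature matrix and label vector."""
    return BehaviourForest(n_trees=n_trees, mtry=mtry, random_state=seed).fit(
        features, labels
    )


def predict(model: BehaviourForest, features) -> tuple[np.ndarray, np.ndarray]:
    """(labels, per-class vote fractions) for new samples."""
    return model.predict(features), model.predict_proba(features)


def oob_error(model: BehaviourForest) -> float:
    """Out-of-bag misclassification fraction of the fitted forest."""
    return model.oob_error()


def permutation_importance(
    model: BehaviourForest, seed: Optional[int] = None
) -> pd.Series:
    """Mean decrease in OOB accuracy per feature, percentage points."""
    return model.permutation_importance(random_state=seed)


def partial_dependence(
    model: BehaviourForest, feature, target_class, grid=None, X=None
) -> tuple[np.ndarray, np.ndarray]:
    """Centred logit-scale partial dependence curve for one class/feature."""
    return model.partial_dependence(feature, target_class, grid=grid, X=X)


def proximity(model: BehaviourForest, X=None) -> np.ndarray:
    """Pairwise same-leaf fraction across trees."""
    return model.proximity(X)


def class_prototypes(
    model: BehaviourForest, n_nbr: int = 20
) -> pd.DataFrame:
    """Proximity-based class prototype feature vectors."""
    return model.class_prototypes(n_nbr=n_nbr)
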