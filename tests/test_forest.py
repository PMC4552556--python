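"""The randomized-tree ensemble: growth, OOB, importance, proximity, PD, JSON."""

import numpy as np
import pandas as pd
import pytest

from castoract.forest import BehaviourForest, train_forest

def two_blob_data(n=60, gap=6.0, d=1, seed=0):
    """Two well-separated classes on the first feature (Bayes error ~ 0)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1.0, size=(2 * n, d))
    X[n:, 0] += gap
    y = np.array(["a"] * n + ["b"] * n)
    return X, y


class TestFit:
    def test_separable_classes_have_tiny_oob_error(self):
        X, y = two_blob_data()
        model = BehaviourForest(n_trees=100, mtry=1, random_state=1).fit(X, y)
        assert model.oob_error_ <= 0.02

    def test_training_set_predictions_perfect_when_separable(self):
        X, y = two_blob_data()
        model = BehaviourForest(n_trees=50, mtry=1, random_state=1).fit(X, y)
        assert (model.predict(X) == y).all()

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        with pytest.raises(ValueError, match="2 classes"):
            BehaviourForest(n_trees=5).fit(X, ["a"] * 20)

    def test_tiny_sample_rejected(self):
        X, y = two_blob_data(n=4)
        with pytest.raises(ValueError, match="10"):
            BehaviourForest(n_trees=5).fit(X, y)

    def test_constant_features_warn_and_leaf_out(self):
        X = np.zeros((20, 2))
        y = ["a"] * 10 + ["b"] * 10
        with pytest.warns(UserWarning, match="constant"):
            model = BehaviourForest(n_trees=5, random_state=0).fit(X, y)
        # degenerate trees are single (majority) leaves
        assert all(len(t.feature) == 1 for t in model.trees_)

    def test_bootstrap_bookkeeping(self):
        X, y = two_blob_data(n=30)
        model = BehaviourForest(n_trees=20, mtry=1, random_state=3).fit(X, y)
        for tree in model.trees_:
            assert len(tree.bootstrap) == len(X)
            assert tree.n_node_samples[0] == len(X)
            leaves = tree.feature == -1
            assert tree.n_node_samples[leaves].min() >= 1

    def test_identical_seeds_identical_forests(self, small_features):
        X, y = small_features
        a = BehaviourForest(n_trees=30, random_state=9).fit(X, y)
        b = BehaviourForest(n_trees=30, random_state=9).fit(X, y)
        assert a.to_json() == b.to_json()
        assert a.oob_error_ == b.oob_error_
        Xq = X.to_numpy()[:25]
        np.testing.assert_array_equal(a.predict(Xq), b.predict(Xq))
        pd.testing.assert_series_equal(
            a.permutation_importance(), b.permutation_importance()
        )


class TestPredict:
    def test_vote_fractions_sum_to_one(self, small_features):
        X, y = small_features
        model = BehaviourForest(n_trees=40, random_state=2).fit(X, y)
        proba = model.predict_proba(X.to_numpy()[:30])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        assert proba.min() >= 0

    def test_feature_dimension_mismatch_rejected(self, small_features):
        X, y = small_features
        model = BehaviourForest(n_trees=10, random_state=2).fit(X, y)
        with pytest.raises(ValueError, match="features"):
            model.predict(np.zeros((3, 5)))

    def test_tie_breaks_to_first_sorted_label(self):
        X, y = two_blob_data(n=30)
        model = BehaviourForest(n_trees=2, mtry=1, random_state=5).fit(X, y)
        proba = model.predict_proba(np.array([[3.0]]))  # midpoint, may tie
        pred = model.predict(np.array([[3.0]]))
        if proba[0, 0] == proba[0, 1]:
            assert pred[0] == "a"


class TestProximity:
    def test_symmetric_unit_diagonal(self, small_features):
        X, y = small_features
        model = BehaviourForest(n_trees=25, random_state=4).fit(X, y)
        prox = model.proximity()
        np.testing.assert_allclose(prox, prox.T)
        np.testing.assert_allclose(np.diag(prox), 1.0)
        assert prox.min() >= 0 and prox.max() <= 1

    def test_identical_samples_have_proximity_one(self):
        X, y = two_blob_data(n=20)
        X[1] = X[0]
        model = BehaviourForest(n_trees=20, mtry=1, random_state=4).fit(X, y)
        prox = model.proximity()
        assert prox[0, 1] == pytest.approx(1.0)

    def test_within_class_proximity_exceeds_between(self, small_features):
        X, y = small_features
        model = BehaviourForest(n_trees=50, random_state=4).fit(X, y)
        prox = model.proximity()
        same = y[:, None] == y[None, :]
        off_diag = ~np.eye(len(y), dtype=bool)
        assert prox[same & off_diag].mean() > prox[~same].mean()


class TestPrototypes:
    def test_tight_clusters_recover_cluster_medians(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0.0, 0.05, size=(40, 3))
        b = rng.normal(5.0, 0.05, size=(40, 3))
        X = np.vstack([a, b])
        y = np.array(["a"] * 40 + ["b"] * 40)
        model = BehaviourForest(n_trees=60, mtry=2, random_state=6).fit(X, y)
        protos = model.class_prototypes(n_nbr=10)
        np.testing.assert_allclose(protos.loc["a"], np.median(a, axis=0), atol=0.05)
        np.testing.assert_allclose(protos.loc["b"], np.median(b, axis=0), atol=0.05)

    def test_prototypes_lie_within_class_feature_ranges(self, small_features):
        X, y = small_features
        model = BehaviourForest(n_trees=50, random_state=6).fit(X, y)
        protos = model.class_prototypes(n_nbr=8)
        Xv = X.to_numpy()
        for label in np.unique(y):
            rows = Xv[y == label]
            p = protos.loc[label].to_numpy()
            assert np.all(p >= rows.min(axis=0) - 1e-12)
            assert np.all(p <= rows.max(axis=0) + 1e-12)

    def test_small_class_shrinks_neighbourhood_with_warning(self):
        X, y = two_blob_data(n=12)
        model = BehaviourForest(n_trees=20, mtry=1, random_state=6).fit(X, y)
        with pytest.warns(UserWarning, match="members"):
            model.class_prototypes(n_nbr=50)


class TestImportance:
    def test_pure_noise_feature_scores_near_zero(self):
        rng = np.random.default_rng(21)
        X, y = two_blob_data(n=80, d=1, seed=21)
        X = np.hstack([X, rng.normal(size=(len(X), 1))])  # appended noise
        model = BehaviourForest(n_trees=200, mtry=1, random_state=7).fit(X, y)
        imp = model.permutation_importance(random_state=7)
        assert abs(imp.iloc[1]) < 1.0  # percentage points
        assert imp.iloc[0] > 10.0


class TestPartialDependence:
    def test_centred_curve_has_zero_weighted_mean(self, small_features):
        X, y = small_features
        model = BehaviourForest(n_trees=30, random_state=8).fit(X, y)
        grid, vals = model.partial_dependence("mean_heave", "walking", n_grid=25)
        col = X["mean_heave"].to_numpy()
        mids = 0.5 * (grid[1:] + grid[:-1])
        w = np.bincount(np.searchsorted(mids, col), minlength=len(grid)).astype(float)
        w /= w.sum()
        assert float((vals * w).sum()) == pytest.approx(0.0, abs=1e-12)

    def test_unknown_class_and_empty_grid_rejected(self, small_features):
        X, y = small_features
        model = BehaviourForest(n_trees=10, random_state=8).fit(X, y)
        with pytest.raises(ValueError, match="unknown class"):
            model.partial_dependence("mean_heave", "flying")
        with pytest.raises(ValueError, match="empty grid"):
            model.partial_dependence("mean_heave", "walking", grid=np.array([]))


class TestSerialisation:
    def test_json_round_trip_preserves_predictions(self, small_features):
        X, y = small_features
        model = train_forest(X, y, n_trees=25, mtry=2, seed=10)
        clone = BehaviourForest.from_json(model.to_json(), X, y)
        Xq = X.to_numpy()
        np.testing.assert_array_equal(model.predict(Xq), clone.predict(Xq))
        np.testing.assert_allclose(
            model.predict_proba(Xq), clone.predict_proba(Xq)
        )
        assert clone.oob_error_ == model.oob_error_

    def test_garbage_json_rejected(self):
        with pytest.raises(ValueError, match="serialised forest"):
            BehaviourForest.from_json('{"format": "something-else"}')
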