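"""Stratified splitting and the randomized-tree ensemble."""

import numpy as np
import pandas as pd
import pytest

import ethogram as e
from ethogram.classifier import _best_split, _grow_tree, _tree_proba
from ethogram.errors import DataError
from ethogram.features import FEATURE_NAMES
from ethogram.rng import substream


def _table(n_per_class, rng, shift=None):
    """A 44-feature table with classes separated along one feature."""
    shift = shift if shift is not None else {"lying": 0.0, "standing": 5.0,
                                             "walking": 10.0}
    rows = []
    for label, n in n_per_class.items():
        X = rng.normal(size=(n, len(FEATURE_NAMES)))
        X[:, 0] += shift[label]
        for x in X:
            row = dict(zip(FEATURE_NAMES, x))
            row["label"] = label
            rows.append(row)
    return pd.DataFrame(rows)


class TestSplit:
    def test_exact_stratification_100_per_class(self, rng):
        t = _table({"lying": 100, "standing": 100, "walking": 100}, rng)
        train, test = e.split_train_test(t, 0.7, seed=0)
        assert train["label"].value_counts().tolist() == [70, 70, 70]
        assert test["label"].value_counts().tolist() == [30, 30, 30]

    def test_exact_stratification_10_per_class(self, rng):
        t = _table({"lying": 10, "standing": 10, "walking": 10}, rng)
        train, test = e.split_train_test(t, 0.7, seed=0)
        assert sorted(train["label"].value_counts()) == [7, 7, 7]
        assert sorted(test["label"].value_counts()) == [3, 3, 3]

    def test_disjoint_exhaustive_and_deterministic(self, rng):
        t = _table({"lying": 37, "standing": 23, "walking": 11}, rng)
        a1, b1 = e.split_train_test(t, 0.7, seed=5)
        a2, b2 = e.split_train_test(t, 0.7, seed=5)
        assert set(a1.index) | set(b1.index) == set(t.index)
        assert set(a1.index).isdisjoint(b1.index)
        assert list(a1.index) == list(a2.index)
        # per-class ratios within one window of the full-table ratio
        for c, n in t["label"].value_counts().items():
            assert abs((a1["label"] == c).sum() - 0.7 * n) <= 1

    def test_missing_class_is_stratification_error(self, rng):
        t = _table({"lying": 10, "standing": 10, "walking": 10}, rng)
        with pytest.raises(DataError, match="walking"):
            e.split_train_test(t[t["label"] != "walking"], 0.7, seed=0)


class TestTrainForest:
    def test_single_class_gives_constant_predictor(self, rng):
        t = _table({"lying": 30, "standing": 1, "walking": 1}, rng)
        t = pd.concat([t[t["label"] == "lying"]], ignore_index=True)
        with pytest.warns(UserWarning, match="single class"):
            model = e.train_forest(t, e.ForestConfig(seed=0))
        labels, proba = e.predict(model, t)
        assert set(labels) == {"lying"}
        np.testing.assert_allclose(proba[:, 0], 1.0)

    def test_separable_classes_reach_perfect_training_accuracy(self, rng):
        """Two Gaussian classes 10 sd apart in one feature; an exhaustive
        threshold search verifies separability first."""
        t = _table({"lying": 100, "standing": 100}, rng,
                   shift={"lying": 0.0, "standing": 10.0})
        x = t[FEATURE_NAMES[0]].to_numpy()
        y = (t["label"] != "lying").to_numpy()
        # oracle: exhaustive threshold search proves a perfect split exists
        thresholds = np.sort(x)
        best = max(
            max((x > thr) .astype(int).__eq__(y).mean(),
                (x <= thr).astype(int).__eq__(y).mean())
            for thr in thresholds
        )
        assert best == 1.0
        model = e.train_forest(t, e.ForestConfig(seed=1))
        labels, _ = e.predict(model, t)
        assert (labels == t["label"]).mean() == 1.0

    def test_fixed_seed_gives_identical_forests(self, rng):
        t = _table({"lying": 40, "standing": 40, "walking": 40}, rng)
        m1 = e.train_forest(t, e.ForestConfig(seed=7))
        m2 = e.train_forest(t, e.ForestConfig(seed=7))
        assert m1.trees == m2.trees

    def test_one_tree_without_bagging_equals_its_single_tree(self, rng):
        t = _table({"lying": 30, "standing": 30, "walking": 30}, rng)
        cfg = e.ForestConfig(n_trees=1, bagging=False, seed=3)
        model = e.train_forest(t, cfg)
        X = t[list(FEATURE_NAMES)].to_numpy(float)
        y = t["label"].map({c: i for i, c in enumerate(e.CLASSES)}).to_numpy()
        tree = _grow_tree(X, y, np.arange(len(X)), substream(3, "tree", 0), cfg, 3)
        assert model.trees == [tree]
        labels, proba = e.predict(model, t)
        direct = np.array([_tree_proba(tree, x) for x in X])
        np.testing.assert_allclose(proba, direct)

    def test_out_of_bag_fraction_approaches_e_inverse(self, rng):
        t = _table({"lying": 4000, "standing": 3000, "walking": 3000}, rng)
        cfg = e.ForestConfig(n_trees=2, random_splits_per_node=4, seed=0)
        model = e.train_forest(t, cfg)
        for frac in model.oob_fractions:
            assert frac == pytest.approx(np.exp(-1), abs=0.02)

    def test_chosen_split_maximizes_gini_gain(self, rng):
        t = _table({"lying": 50, "standing": 50, "walking": 50}, rng)
        X = t[list(FEATURE_NAMES)].to_numpy(float)
        y = t["label"].map({c: i for i, c in enumerate(e.CLASSES)}).to_numpy()
        cfg = e.ForestConfig(seed=0)
        best, candidates = _best_split(
            X, y, np.arange(len(X)), substream(0, "audit"), cfg, 3,
            return_candidates=True,
        )
        assert best is not None
        gains = [g for _, _, g in candidates if np.isfinite(g)]
        assert best[2] == pytest.approx(np.nanmax(gains))
        assert all(best[2] >= g - 1e-12 for g in gains)

    def test_leaf_frequencies_are_probability_vectors(self, rng):
        t = _table({"lying": 30, "standing": 30, "walking": 30}, rng)
        model = e.train_forest(t, e.ForestConfig(seed=2))

        def walk(node):
            if "freq" in node:
                assert sum(node["counts"]) >= 1
                assert sum(node["freq"]) == pytest.approx(1.0)
            else:
                walk(node["left"])
                walk(node["right"])

        for tree in model.trees:
            walk(tree)


class TestPredict:
    def test_probabilities_sum_to_one(self, rng):
        t = _table({"lying": 30, "standing": 30, "walking": 30}, rng)
        model = e.train_forest(t, e.ForestConfig(seed=4))
        _, proba = e.predict(model, t)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_unanimous_trees_give_probability_one(self, rng):
        # without bagging every tree sees all samples and reaches a pure
        # leaf for each -> unanimity by construction
        t = _table({"lying": 50, "standing": 50, "walking": 50}, rng,
                   shift={"lying": 0.0, "standing": 50.0, "walking": 100.0})
        model = e.train_forest(t, e.ForestConfig(seed=0, bagging=False))
        labels, proba = e.predict(model, t)
        assert proba.max(axis=1).min() == pytest.approx(1.0)
        assert (labels == t["label"]).all()

    def test_missing_features_rejected(self, rng):
        t = _table({"lying": 5, "standing": 5, "walking": 5}, rng)
        model = e.train_forest(t, e.ForestConfig(seed=0))
        with pytest.raises(Exception):
            e.predict(model, t.drop(columns=[FEATURE_NAMES[0]]))


class TestSerialization:
    def test_model_json_round_trip(self, tmp_path, rng):
        t = _table({"lying": 20, "standing": 20, "walking": 20}, rng)
        model = e.train_forest(t, e.ForestConfig(seed=6))
        path = e.save_model(model, tmp_path / "model.json")
        back = e.load_model(path)
        assert back.trees == model.trees
        assert back.config == model.config
        l1, p1 = e.predict(model, t)
        l2, p2 = e.predict(back, t)
        assert (l1 == l2).all()
        np.testing.assert_array_equal(p1, p2)


def test_agrees_with_extra_trees_on_separable_data(rng):
    """Independent cross-check: sklearn's extremely-randomized trees,
    trained on the same task, classify well-separated classes at the
    same (near-perfect) held-out accuracy and agree on the vast
    majority of windows."""
    from sklearn.ensemble import ExtraTreesClassifier

    t = _table({"lying": 150, "standing": 150, "walking": 150}, rng,
               shift={"lying": 0.0, "standing": 20.0, "walking": 40.0})
    train, test = e.split_train_test(t, 0.7, seed=0)
    model = e.train_forest(train, e.ForestConfig(seed=0))
    ours, _ = e.predict(model, test)
    skl = ExtraTreesClassifier(n_estimators=64, random_state=0).fit(
        train[list(FEATURE_NAMES)], train["label"]
    )
    theirs = skl.predict(test[list(FEATURE_NAMES)])
    assert (ours == test["label"]).mean() >= 0.95
    assert (theirs == test["label"]).mean() >= 0.95
    assert (ours == theirs).mean() >= 0.95
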