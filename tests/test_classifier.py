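import numpy as np
import pandas as pd
import pytest

from phagelink.classifier import (
    cross_dataset_grid,
    feature_importances,
    randomized_search,
    select_final,
    split_70_30,
    train_final,
)
from phagelink.evaluation import roc_curve_and_auc
from phagelink.pair_features import FEATURE_COLUMNS


def toy_frame(n_pos=102, n_neg=102, seed=0, signal=True):
    """A balanced frame whose first two features separate the classes."""
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    labels = np.array([1] * n_pos + [0] * n_neg)
    df = pd.DataFrame(
        rng.uniform(size=(n, len(FEATURE_COLUMNS))), columns=FEATURE_COLUMNS
    )
    if signal:
        df["co_occurrence"] = np.where(
            labels == 1, rng.uniform(0.6, 1.0, n), rng.uniform(0.0, 0.4, n)
        )
        df["avg_distance"] = np.where(
            labels == 1, rng.uniform(0, 500, n), rng.uniform(5_000, 40_000, n)
        )
    df["pvog_a"] = [f"A{i}" for i in range(n)]
    df["pvog_b"] = [f"B{i}" for i in range(n)]
    df["label"] = labels
    return df


class TestSplit7030:
    def test_204_pairs_give_62_holdout(self):
        train, holdout = split_70_30(toy_frame(), seed=0)
        assert (len(train), len(holdout)) == (142, 62)
        assert holdout["label"].sum() == 31  # stratified

    def test_deterministic(self):
        df = toy_frame()
        a = split_70_30(df, seed=4)[1]
        b = split_70_30(df, seed=4)[1]
        pd.testing.assert_frame_equal(a, b)

    def test_single_class_rejected(self):
        df = toy_frame()
        df["label"] = 1
        with pytest.raises(ValueError, match="both classes"):
            split_70_30(df, seed=0)


class TestRandomizedSearch:
    def test_single_iteration_returns_sampled_config(self):
        df = toy_frame(n_pos=30, n_neg=30)
        space = {"n_estimators": [10], "max_depth": [3]}
        params = randomized_search(df, space=space, n_iter=1, seed=0)
        assert params == {"n_estimators": 10, "max_depth": 3}

    def test_deterministic_under_seed(self):
        df = toy_frame(n_pos=40, n_neg=40)
        space = {"n_estimators": [10, 20], "max_depth": [2, 5, None]}
        a = randomized_search(df, space=space, n_iter=5, seed=3)
        b = randomized_search(df, space=space, n_iter=5, seed=3)
        assert a == b

    def test_depth_limited_configuration_loses_on_xor_data(self):
        """Labels are the XOR of two features, separable only at depth >= 2:
        the search must prefer the deeper configuration."""
        rng = np.random.default_rng(8)
        n = 160
        df = pd.DataFrame(
            rng.uniform(size=(n, len(FEATURE_COLUMNS))), columns=FEATURE_COLUMNS
        )
        x0 = df["co_occurrence"] > 0.5
        x1 = df["avg_distance"] > 0.5
        df["label"] = (x0 ^ x1).astype(int)
        space = {
            "n_estimators": [50],
            "max_depth": [1, 6],
            "max_features": [None],
        }
        params = randomized_search(df, space=space, n_iter=6, seed=1)
        assert params["max_depth"] == 6


class TestTrainFinal:
    def test_separable_data_fits_perfectly(self):
        df = toy_frame(n_pos=40, n_neg=40)
        model = train_final(df, {"max_depth": None}, seed=0, n_trees=100)
        proba = model.predict_proba(df[FEATURE_COLUMNS].to_numpy())
        assert ((proba > 0.5).astype(int) == df["label"].to_numpy()).all()

    def test_final_forest_has_500_trees_by_default(self):
        df = toy_frame(n_pos=20, n_neg=20)
        model = train_final(df, {"n_estimators": 10}, seed=0)
        assert model.estimator.n_estimators == 500

    def test_deterministic_predictions(self):
        df = toy_frame(n_pos=30, n_neg=30)
        X = df[FEATURE_COLUMNS].to_numpy()
        p1 = train_final(df, {}, seed=5, n_trees=50).predict_proba(X)
        p2 = train_final(df, {}, seed=5, n_trees=50).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_label_shuffle_null_auroc_near_half(self):
        """With labels shuffled, holdout AUROC should hover around 0.5."""
        rng = np.random.default_rng(42)
        aurocs = []
        for _ in range(20):
            df = toy_frame(n_pos=60, n_neg=60, seed=1)
            df["label"] = rng.permutation(df["label"].to_numpy())
            train, holdout = split_70_30(df, seed=int(rng.integers(1000)))
            model = train_final(train, {}, seed=0, n_trees=50)
            proba = model.predict_proba(holdout[FEATURE_COLUMNS].to_numpy())
            _, auroc = roc_curve_and_auc(holdout["label"].to_numpy(), proba)
            aurocs.append(auroc)
        assert abs(float(np.mean(aurocs)) - 0.5) < 0.15


class TestCrossDatasetGrid:
    CANDIDATES = {"N1": {"n_estimators": 20}, "N2": {"n_estimators": 20, "max_depth": 4}}
    DATASETS = {
        "N1": toy_frame(n_pos=40, n_neg=40, seed=1),
        "N2": toy_frame(n_pos=40, n_neg=40, seed=2),
    }

    def test_shape_and_metrics(self):
        grid = cross_dataset_grid(self.CANDIDATES, self.DATASETS, seed=0)
        assert len(grid) == 4
        for metric in ("accuracy", "precision", "recall", "f1", "auroc"):
            assert metric in grid.columns

    def test_own_dataset_cell_uses_fresh_split(self):
        grid = cross_dataset_grid(self.CANDIDATES, self.DATASETS, seed=0)
        fresh = grid[grid["fresh_split"]]
        assert set(zip(fresh["candidate"], fresh["dataset"])) == {
            ("N1", "N1"),
            ("N2", "N2"),
        }

    def test_deterministic_under_seed(self):
        a = cross_dataset_grid(self.CANDIDATES, self.DATASETS, seed=0)
        b = cross_dataset_grid(self.CANDIDATES, self.DATASETS, seed=0)
        pd.testing.assert_frame_equal(a, b)


class TestSelectFinal:
    @staticmethod
    def grid(rows):
        return pd.DataFrame(rows, columns=["candidate", "dataset", "auroc", "accuracy", "f1"])

    def test_dominant_candidate_selected(self):
        grid = self.grid(
            [("N1", "N1", 0.9, 0.8, 0.8), ("N1", "N2", 0.9, 0.8, 0.8),
             ("N2", "N1", 0.7, 0.7, 0.7), ("N2", "N2", 0.7, 0.7, 0.7)]
        )
        assert select_final(grid) == "N1"

    def test_auroc_tie_broken_by_accuracy(self):
        grid = self.grid(
            [("N1", "N1", 0.8, 0.70, 0.8), ("N2", "N1", 0.8, 0.75, 0.8)]
        )
        assert select_final(grid) == "N2"

    def test_full_tie_broken_lexicographically(self):
        grid = self.grid(
            [("N2", "N1", 0.8, 0.8, 0.8), ("N1", "N1", 0.8, 0.8, 0.8)]
        )
        assert select_final(grid) == "N1"


class TestFeatureImportances:
    def test_normalized_and_descending(self):
        df = toy_frame(n_pos=40, n_neg=40)
        model = train_final(df, {}, seed=0, n_trees=50)
        ranked = feature_importances(model)
        values = [v for _, v in ranked]
        assert sum(values) == pytest.approx(1.0, abs=1e-9)
        assert values == sorted(values, reverse=True)

    def test_planted_single_signal_ranks_first(self):
        wins = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                rng.uniform(size=(160, len(FEATURE_COLUMNS))), columns=FEATURE_COLUMNS
            )
            labels = rng.integers(0, 2, 160)
            df["co_occurrence"] = labels + rng.normal(0, 0.1, 160)
            df["label"] = labels
            model = train_final(df, {}, seed=seed, n_trees=50)
            if feature_importances(model)[0][0] == "co_occurrence":
                wins += 1
        assert wins == 3

    def test_constant_feature_zero_importance(self):
        df = toy_frame(n_pos=40, n_neg=40)
        df["f_div"] = 0.0
        model = train_final(df, {}, seed=0, n_trees=50)
        assert dict(feature_importances(model))["f_div"] == 0.0
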