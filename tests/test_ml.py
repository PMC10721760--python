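"""Cleaning, Cluster-Centroids undersampling, classifiers, clade importance."""

import numpy as np
import pandas as pd
import pytest

from plantpp import (ClassifierSpec, CladeMap, EvalMetrics, MLDataset,
                     clade_feature_importance, clean,
                     cluster_centroids_undersample, train_and_eval)
from plantpp.ml import stratified_split


def gaussian_frame(n, d, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(scale=scale, size=(n, d)),
                        index=[f"g{i}" for i in range(n)],
                        columns=[f"s{j}" for j in range(d)])


class TestClean:
    def test_three_sigma_outlier_nulled_then_interpolated(self):
        # one value far outside mu +/- 3 sd; flanking features make the
        # row [1, ., 3] interpolate to the exact midpoint 2; extra
        # well-behaved features keep the row under the 20% missing cap
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.uniform(size=(100, 6)),  # bounded: |z| < 3 throughout
                         columns=[f"s{j}" for j in range(6)])
        X["s0"] = 1.0 + np.linspace(0, 0.01, 100)
        X["s2"] = 3.0 + np.linspace(0, 0.01, 100)
        col = np.zeros(100)
        col[50] = 100.0        # z ~ 9.9 against the column's own stats
        X["s1"] = col
        out = clean(X).X
        assert out.loc[50, "s1"] == pytest.approx(
            (X.loc[50, "s0"] + X.loc[50, "s2"]) / 2)
        assert out.loc[0, "s1"] == 0.0

    def test_missing_fraction_boundary_strict(self):
        n = 20
        base = gaussian_frame(n, 1, seed=1)
        kept = base.copy()
        kept["exact"] = np.where(np.arange(n) < 4, np.nan, 1.0 + base["s0"] * 0.01)
        kept["over"] = np.where(np.arange(n) < 5, np.nan, 1.0 + base["s0"] * 0.01)
        out = clean(kept).X
        assert "exact" in out.columns      # 20% missing: kept
        assert "over" not in out.columns   # 25% missing: dropped

    def test_edge_gaps_take_nearest_value(self):
        X = pd.DataFrame([[np.nan, 2.0, 4.0, np.nan]] * 10,
                         columns=list("abcd"), dtype=float)
        X += np.arange(10)[:, None] * 0.01  # avoid degenerate columns
        # >20% missing columns a and d would be dropped; keep them by
        # making missingness row-local instead
        X2 = gaussian_frame(20, 5, seed=2)
        X2.iloc[3, 0] = np.nan   # leading gap
        X2.iloc[7, 4] = np.nan   # trailing gap
        out = clean(X2).X
        assert out.iloc[3, 0] == pytest.approx(X2.iloc[3, 1])
        assert out.iloc[7, 4] == pytest.approx(X2.iloc[7, 3])

    def test_idempotent_on_own_output(self):
        # bounded base data (max |z| ~ sqrt(3)) plus one planted outlier:
        # the first pass nulls and interpolates it, the second changes
        # nothing
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.uniform(size=(200, 8)),
                         columns=[f"s{j}" for j in range(8)])
        X.iloc[0, 3] = 50.0
        once = clean(X).X
        twice = clean(once).X
        pd.testing.assert_frame_equal(once, twice)

    def test_all_features_dropped_raises(self):
        X = pd.DataFrame({"s0": [np.nan] * 8 + [1.0, 2.0]})
        with pytest.raises(ValueError, match="features"):
            clean(X)


class TestUndersampling:
    def test_counts_and_minority_preserved(self):
        X = gaussian_frame(13, 4, seed=4)
        y = pd.Series([1] * 3 + [0] * 10, index=X.index)
        out = cluster_centroids_undersample(MLDataset(X, y), seed=0)
        assert out.y.value_counts().tolist() == [3, 3]
        pd.testing.assert_frame_equal(out.X.loc[X.index[:3]], X.iloc[:3])

    def test_already_balanced_is_identity(self):
        X = gaussian_frame(10, 3, seed=5)
        y = pd.Series([0] * 5 + [1] * 5, index=X.index)
        ds = MLDataset(X, y)
        out = cluster_centroids_undersample(ds, seed=0)
        assert out is ds

    def test_degenerate_majority_centroids_equal_the_row(self):
        row = np.array([1.0, 2.0, 3.0])
        X = pd.DataFrame([row] * 4 + [[9, 9, 9], [8, 8, 8]],
                         index=[f"g{i}" for i in range(6)], columns=list("abc"))
        y = pd.Series([0, 0, 0, 0, 1, 1], index=X.index)
        out = cluster_centroids_undersample(MLDataset(X, y), seed=0)
        centroids = out.X.loc[out.y == 0].to_numpy()
        assert np.allclose(centroids, row)

    def test_single_class_raises(self):
        X = gaussian_frame(5, 2, seed=6)
        with pytest.raises(ValueError, match="class"):
            cluster_centroids_undersample(MLDataset(X, pd.Series([1] * 5, index=X.index)))


class TestMetrics:
    def test_confusion_arithmetic(self):
        m = EvalMetrics.from_confusion(tp=3, fp=1, fn=1, tn=5)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.75)
        assert m.f1 == pytest.approx(0.75)
        assert m.accuracy == pytest.approx(0.8)

    def test_perfect_predictions(self):
        y = np.array([0, 1, 1, 0, 1])
        m = EvalMetrics.from_predictions(y, y)
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_zero_denominators(self):
        m = EvalMetrics.from_confusion(tp=0, fp=0, fn=2, tn=3)
        assert m.precision == 0.0 and m.f1 == 0.0

    def test_identities_hold_on_random_confusions(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            tp, fp, fn, tn = rng.integers(0, 20, size=4)
            if tp + fp + fn + tn == 0:
                continue
            m = EvalMetrics.from_confusion(int(tp), int(fp), int(fn), int(tn))
            assert m.accuracy == pytest.approx((tp + tn) / (tp + fp + fn + tn))
            if m.precision + m.recall > 0:
                assert m.f1 == pytest.approx(
                    2 * m.precision * m.recall / (m.precision + m.recall))


def separable_dataset(n=500, d=20, separation=5.0, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = rng.normal(size=(n, d))
    X[:, 0] += y * separation
    frame = pd.DataFrame(X, index=[f"g{i}" for i in range(n)],
                         columns=[f"s{j}" for j in range(d)])
    return MLDataset(frame, pd.Series(y, index=frame.index))


class TestTrainAndEval:
    def test_separable_data_learned_by_rf(self):
        train, test = stratified_split(separable_dataset(seed=8), seed=8)
        metrics, model = train_and_eval(train, test, ClassifierSpec(kind="rf", seed=8))
        # margin-classifier oracle: threshold on the separating feature
        thresh = 2.5
        oracle = (test.X["s0"] > thresh).astype(int)
        oracle_acc = (oracle == test.y).mean()
        assert oracle_acc >= 0.99
        assert metrics.accuracy >= 0.95

    def test_single_class_training_raises(self):
        ds = separable_dataset(n=50, seed=9)
        ds.y[:] = 1
        train, test = MLDataset(ds.X[:40], ds.y[:40]), MLDataset(ds.X[40:], ds.y[40:])
        with pytest.raises(ValueError, match="single class"):
            train_and_eval(train, test, ClassifierSpec(kind="rf"))

    def test_reproducible_with_fixed_seed(self):
        train, test = stratified_split(separable_dataset(seed=10), seed=10)
        spec = ClassifierSpec(kind="rf", seed=10)
        m1, _ = train_and_eval(train, test, spec)
        m2, _ = train_and_eval(train, test, spec)
        assert m1 == m2


class TestCladeImportance:
    class UniformModel:
        def __init__(self, d):
            self.feature_importances_ = np.full(d, 1.0 / d)

    def test_uniform_importances_give_equal_means(self):
        features = [f"s{i}" for i in range(12)]
        mapping = {f: ("A" if i < 6 else "B") for i, f in enumerate(features)}
        out = clade_feature_importance(self.UniformModel(12), features,
                                       CladeMap(mapping, min_species=1))
        assert out["mean_importance"].nunique() == 1

    def test_single_species_clade_has_zero_se(self):
        features = ["s0", "s1", "s2"]
        mapping = {"s0": "A", "s1": "B", "s2": "B"}
        out = clade_feature_importance(self.UniformModel(3), features,
                                       CladeMap(mapping, min_species=1))
        assert out.loc["A", "se"] == 0.0 and out.loc["A", "n_species"] == 1

    def test_planted_clade_signal_ranks_top(self):
        """Labels driven only by clade A's species put clade A's mean
        importance on top, across 10 seeds."""
        features = [f"s{j}" for j in range(30)]
        mapping = {f: f"clade{j // 10}" for j, f in enumerate(features)}
        cm = CladeMap(mapping, min_species=1)
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(300, 30)), columns=features)
            y = (X[[f"s{j}" for j in range(10)]].mean(axis=1) > 0).astype(int)
            train = MLDataset(X, y)
            _, model = train_and_eval(train, train, ClassifierSpec(kind="rf", seed=seed))
            out = clade_feature_importance(model, features, cm)
            wins += out["mean_importance"].idxmax() == "clade0"
        assert wins == 10
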