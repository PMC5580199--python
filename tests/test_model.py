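"""Risk classifier: CV partitioning, determinism, leakage, prediction
contracts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from asthmawatch.features import FEATURE_ORDER, FeatureVector
from asthmawatch.labels import RiskLevel
from asthmawatch.model import (
    ModelBundle,
    chance_level,
    crossvalidate,
    predict,
    train,
)

FAST_GRID = {"model__n_estimators": [50]}


def make_blobs(n_per_class=20, sep=8.0, seed=0):
    """Three well-separated Gaussian clusters in feature space."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for k, level in enumerate(["low", "medium", "high"]):
        center = np.full(len(FEATURE_ORDER), k * sep)
        rows.append(center + rng.normal(0, 0.5, (n_per_class, len(FEATURE_ORDER))))
        labels += [level] * n_per_class
    X = pd.DataFrame(np.vstack(rows), columns=FEATURE_ORDER)
    return X, labels


class TestChanceLevel:
    @pytest.mark.parametrize("k,expected", [(3, 1 / 3), (2, 0.5), (4, 0.25)])
    def test_uniform_random_predictor_accuracy(self, k, expected):
        assert chance_level(k) == pytest.approx(expected)

    def test_fewer_than_two_classes_rejected(self):
        with pytest.raises(ValueError):
            chance_level(1)


class TestCrossvalidate:
    def test_separable_classes_reach_perfect_accuracy(self):
        X, y = make_blobs()
        result = crossvalidate(X, y, grid=FAST_GRID, seed=1)
        assert result.mean == pytest.approx(1.0)

    def test_fold_sizes_differ_by_at_most_one(self):
        X, y = make_blobs(n_per_class=21)  # 63 samples over 10 folds
        result = crossvalidate(X, y, grid=FAST_GRID, seed=2)
        sizes = [len(idx) for idx in result.fold_indices]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == result.n_samples

    def test_each_sample_validated_exactly_once(self):
        X, y = make_blobs()
        result = crossvalidate(X, y, grid=FAST_GRID, seed=3)
        seen = np.concatenate(result.fold_indices)
        assert sorted(seen) == list(range(len(y)))

    def test_same_seed_reproduces_folds_and_result(self):
        X, y = make_blobs()
        a = crossvalidate(X, y, grid=FAST_GRID, seed=4)
        b = crossvalidate(X, y, grid=FAST_GRID, seed=4)
        assert a.fold_accuracies == b.fold_accuracies
        assert all(np.array_equal(i, j) for i, j in zip(a.fold_indices, b.fold_indices))
        assert np.array_equal(a.confusion, b.confusion)

    def test_confusion_matrix_total_equals_n_samples(self):
        X, y = make_blobs()
        result = crossvalidate(X, y, grid=FAST_GRID, seed=5)
        assert result.confusion.sum() == result.n_samples

    def test_mean_and_sd_recomputable_from_folds(self):
        X, y = make_blobs()
        result = crossvalidate(X, y, grid=FAST_GRID, seed=6)
        assert result.mean == pytest.approx(np.mean(result.fold_accuracies))
        assert result.sd == pytest.approx(np.std(result.fold_accuracies, ddof=1))

    def test_too_few_samples_rejected(self):
        X, y = make_blobs(n_per_class=3)
        with pytest.raises(ValueError):
            crossvalidate(X[:9], y[:9], grid=FAST_GRID, seed=0)

    def test_single_class_rejected(self):
        X, _ = make_blobs()
        with pytest.raises(ValueError):
            crossvalidate(X, ["low"] * len(X), grid=FAST_GRID, seed=0)

    def test_validation_labels_never_touch_training_fits(self):
        """Permuting one validation fold's labels must leave that fold's
        predictions unchanged (the fold's samples never enter training for
        itself)."""
        X, y = make_blobs(seed=11)
        base = crossvalidate(X, y, grid=FAST_GRID, seed=7)
        fold0 = base.fold_indices[0]
        y_perm = list(y)
        rng = np.random.default_rng(0)
        permuted = rng.permutation([y[i] for i in fold0])
        for i, lbl in zip(fold0, permuted):
            y_perm[i] = lbl
        # only fold 0's validation labels changed; its training data is the
        # other folds, which are untouched
        again = crossvalidate(X, y_perm, grid=FAST_GRID, seed=7)
        assert np.array_equal(base.fold_predictions[0], again.fold_predictions[0])

    def test_naive_bayes_baseline_runs_in_same_harness(self):
        X, y = make_blobs()
        result = crossvalidate(X, y, grid=FAST_GRID, seed=8, estimator="nb")
        assert result.mean == pytest.approx(1.0)


class TestTrainPredict:
    def test_training_points_from_separated_clusters_predict_themselves(self):
        X, y = make_blobs()
        bundle = train(X, y, seed=1)
        for i in [0, 25, 45]:
            label, _ = predict(bundle, X.iloc[i].to_numpy())
            assert label.value == y[i]

    def test_bundle_round_trip_predicts_identically(self, tmp_path):
        X, y = make_blobs()
        bundle = train(X, y, seed=2)
        path = tmp_path / "model.bundle"
        bundle.save(path)
        loaded = ModelBundle.load(path)
        probes = X.iloc[::7].to_numpy()
        for row in probes:
            assert predict(bundle, row) == predict(loaded, row)

    def test_refit_same_seed_and_data_is_prediction_identical(self):
        X, y = make_blobs()
        a, b = train(X, y, seed=3), train(X, y, seed=3)
        assert a.training_fingerprint == b.training_fingerprint
        for row in X.iloc[::5].to_numpy():
            assert predict(a, row) == predict(b, row)

    def test_probabilities_sum_to_one_on_random_probes(self):
        X, y = make_blobs()
        bundle = train(X, y, seed=4)
        rng = np.random.default_rng(5)
        for _ in range(100):
            _, probs = predict(bundle, rng.normal(0, 10, len(FEATURE_ORDER)))
            assert sum(probs.values()) == pytest.approx(1.0)

    def test_probability_ties_break_toward_higher_risk(self):
        """A forest of one stump trained on a two-class coin-flip feature
        yields exact 50/50 probabilities on the decision boundary."""
        rng = np.random.default_rng(6)
        n = 40
        X = pd.DataFrame(0.0, index=range(n), columns=list(FEATURE_ORDER))
        X["percent_pef"] = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        y = ["medium"] * (n // 2) + ["high"] * (n // 2)
        bundle = train(
            X, y, hyperparameters={"model__n_estimators": 2, "model__max_depth": 1},
            seed=7,
        )
        probe = X.iloc[0].to_numpy().copy()
        probe[1] = 0.5  # straddle the split
        label, probs = predict(bundle, probe)
        if probs["medium"] == probs["high"]:
            assert label is RiskLevel.HIGH

    def test_missing_feature_imputed_from_stored_median(self):
        X, y = make_blobs()
        bundle = train(X, y, seed=8)
        feats = {name: float(X.iloc[0][name]) for name in FEATURE_ORDER}
        feats["percent_pef"] = float("nan")
        fv = FeatureVector(0.0, 60.0, feats)
        label, probs = predict(bundle, fv)
        assert "percent_pef" in fv.missing
        assert sum(probs.values()) == pytest.approx(1.0)
        assert label.value == y[0]

    def test_wrong_length_input_rejected(self):
        X, y = make_blobs()
        bundle = train(X, y, seed=9)
        with pytest.raises(ValueError):
            predict(bundle, np.zeros(5))
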