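"""Model selection: MCC, the two scoring modes, folds, and grid search."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from pxrml import selection
from pxrml.selection import (
    CVResult,
    ModelConfig,
    cross_validate,
    fit_final,
    grid_search,
    mcc,
    mcc_from_predictions,
    predict,
    score_gap_penalized,
    score_validation,
    select_winner,
    stratified_folds,
)


def brute_force_mcc(tp, fp, fn, tn):
    """Independent closed-form evaluation, written from the definition."""
    num = tp * tn - fp * fn
    den = math.sqrt(tp + fp) * math.sqrt(tp + fn) * math.sqrt(tn + fp) * math.sqrt(tn + fn)
    return 0.0 if den == 0 else num / den


class TestMCC:
    def test_perfect_classifier(self):
        assert mcc(5, 0, 0, 5) == 1.0

    def test_inverted_classifier(self):
        assert mcc(0, 5, 5, 0) == -1.0

    def test_hand_worked_example(self):
        # (3,1,2,4): (3*4 - 1*2) / sqrt(4*5*5*6) = 10/sqrt(600)
        assert mcc(3, 1, 2, 4) == pytest.approx(10 / math.sqrt(600), abs=1e-12)

    def test_matches_brute_force_on_all_small_confusion_matrices(self):
        for tp, fp, fn, tn in itertools.product(range(6), repeat=4):
            assert mcc(tp, fp, fn, tn) == pytest.approx(
                brute_force_mcc(tp, fp, fn, tn), abs=1e-12
            )

    def test_invariant_under_class_relabeling(self):
        # swapping what we call "positive" leaves the correlation unchanged
        for tp, fp, fn, tn in itertools.product(range(5), repeat=4):
            assert mcc(tp, fp, fn, tn) == pytest.approx(mcc(tn, fn, fp, tp), abs=1e-12)

    def test_negates_under_prediction_inversion(self):
        for tp, fp, fn, tn in itertools.product(range(5), repeat=4):
            assert mcc(tp, fp, fn, tn) == pytest.approx(-mcc(fn, tn, tp, fp), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mcc(-1, 0, 0, 1)

    def test_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            tp, fp, fn, tn = rng.integers(0, 50, size=4)
            assert -1.0 <= mcc(int(tp), int(fp), int(fn), int(tn)) <= 1.0


class TestScores:
    def test_validation_score_is_mean(self):
        cv = CVResult(mcc_train=[0.9, 0.9], mcc_val=[0.2, 0.6])
        assert score_validation(cv) == pytest.approx(0.4)

    def test_validation_constant_folds(self):
        cv = CVResult(mcc_train=[1.0] * 5, mcc_val=[0.4] * 5)
        assert score_validation(cv) == pytest.approx(0.4)

    def test_gap_score_hand_example(self):
        # val (0.5, 0.3), train (0.9, 0.7): 0.4 - 0.4 = 0.0
        cv = CVResult(mcc_train=[0.9, 0.7], mcc_val=[0.5, 0.3])
        assert score_gap_penalized(cv) == pytest.approx(0.0, abs=1e-12)

    def test_gap_vanishes_when_train_equals_val(self):
        cv = CVResult(mcc_train=[0.3, 0.5, 0.7], mcc_val=[0.3, 0.5, 0.7])
        assert score_gap_penalized(cv) == pytest.approx(score_validation(cv), abs=1e-12)

    def test_signed_gap_rewards_val_above_train(self):
        # k=1, val 0.5, train 0.4: 0.5 - (-0.1) = 0.6 — the penalty is signed
        cv = CVResult(mcc_train=[0.4], mcc_val=[0.5])
        assert score_gap_penalized(cv) == pytest.approx(0.6, abs=1e-12)

    def test_algebraic_identity_on_random_results(self):
        # gap score == (1/k) * sum(2*val_i - train_i)
        rng = np.random.default_rng(42)
        for _ in range(1000):
            k = int(rng.integers(2, 11))
            train = rng.uniform(-1, 1, k)
            val = rng.uniform(-1, 1, k)
            cv = CVResult(mcc_train=train.tolist(), mcc_val=val.tolist())
            assert score_gap_penalized(cv) == pytest.approx(
                float(np.mean(2 * val - train)), abs=1e-12
            )

    def test_gap_score_never_above_validation_when_overfitting(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            k = int(rng.integers(2, 8))
            val = rng.uniform(-1, 1, k)
            train = val + rng.uniform(0, 0.5, k)  # train >= val everywhere
            cv = CVResult(mcc_train=train.tolist(), mcc_val=val.tolist())
            assert score_gap_penalized(cv) <= score_validation(cv) + 1e-12


class TestStratifiedFolds:
    def test_partition_property(self):
        labels = np.array([1] * 40 + [0] * 160)
        folds = stratified_folds(labels, k=5, seed=0)
        assert len(folds) == 200
        assert set(folds.tolist()) == {0, 1, 2, 3, 4}

    def test_reproducible_for_fixed_seed(self):
        labels = np.array([1] * 30 + [0] * 70)
        assert np.array_equal(
            stratified_folds(labels, 5, seed=3), stratified_folds(labels, 5, seed=3)
        )

    def test_per_fold_class_counts_near_global_ratio(self):
        # 202/739 imbalance: activator counts per fold must be floor/ceil of 202/5
        rng = np.random.default_rng(0)
        labels = np.array([1] * 202 + [0] * 739)
        rng.shuffle(labels)
        folds = stratified_folds(labels, k=5, seed=1)
        for i in range(5):
            n_act = int(labels[folds == i].sum())
            assert n_act in (40, 41)

    def test_too_small_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(np.array([1, 1, 0, 0, 0, 0, 0]), k=5)


def _separable_data(n=120, seed=0):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.4).astype(int)
    X = rng.normal(size=(n, 4))
    X[:, 0] += 8 * y  # wide margin on one coordinate
    return X, y


class TestCrossValidate:
    def test_separable_data_perfect_validation(self):
        X, y = _separable_data()
        folds = stratified_folds(y, k=4, seed=0)
        config = ModelConfig.make(
            "random_forest", seed=0, n_estimators=50, min_samples_leaf=1
        )
        cv = cross_validate(config, X, y, folds)
        assert cv.k == 4
        assert all(m == pytest.approx(1.0) for m in cv.mcc_val)

    def test_interpolating_model_memorizes_training_folds(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 6))
        y = (rng.random(80) < 0.5).astype(int)  # pure noise labels
        folds = stratified_folds(y, k=4, seed=0)
        config = ModelConfig.make(
            "random_forest", seed=0, n_estimators=100, min_samples_leaf=1
        )
        cv = cross_validate(config, X, y, folds)
        assert all(m == pytest.approx(1.0) for m in cv.mcc_train)

    def test_constant_predictor_scores_zero(self):
        # all-negative predictions hit the zero-denominator convention
        y_true = np.array([1, 1, 0, 0, 0])
        y_pred = np.zeros(5, dtype=int)
        assert mcc_from_predictions(y_true, y_pred) == 0.0


class TestGridSearch:
    def test_single_config_wins(self):
        X, y = _separable_data()
        folds = stratified_folds(y, k=3, seed=0)
        grid = [ModelConfig.make("random_forest", seed=0, n_estimators=20)]
        outcome = grid_search(grid, X, y, folds, "validation")
        assert outcome.best_config is grid[0]

    def test_modes_disagree_on_hand_built_table(self):
        # X: val 0.50 / train 0.90 — validation mode's pick (0.50 > 0.45)
        # Y: val 0.45 / train 0.50 — gap mode's pick   (0.40 > 0.10)
        cfg_x = ModelConfig.make("random_forest", seed=0, min_samples_leaf=1)
        cfg_y = ModelConfig.make("random_forest", seed=0, min_samples_leaf=8)
        table = [
            {
                "index": 0,
                "config": cfg_x,
                "cv": CVResult([0.90], [0.50]),
                "score_validation": 0.50,
                "score_gap_penalized": 0.10,
            },
            {
                "index": 1,
                "config": cfg_y,
                "cv": CVResult([0.50], [0.45]),
                "score_validation": 0.45,
                "score_gap_penalized": 0.40,
            },
        ]
        assert select_winner(table, "validation").best_config is cfg_x
        assert select_winner(table, "gap_penalized").best_config is cfg_y

    def test_score_tie_broken_toward_regularization(self):
        cfg_deep = ModelConfig.make("random_forest", seed=0, min_samples_leaf=1)
        cfg_shallow = ModelConfig.make("random_forest", seed=0, min_samples_leaf=64)
        row = {"cv": CVResult([0.5], [0.5]), "score_validation": 0.5,
               "score_gap_penalized": 0.5}
        table = [
            {"index": 0, "config": cfg_deep, **row},
            {"index": 1, "config": cfg_shallow, **row},
        ]
        assert select_winner(table, "validation").best_config is cfg_shallow
        cfg_small_c = ModelConfig.make("svm", seed=0, C=0.1)
        cfg_big_c = ModelConfig.make("svm", seed=0, C=10.0)
        table = [
            {"index": 0, "config": cfg_big_c, **row},
            {"index": 1, "config": cfg_small_c, **row},
        ]
        assert select_winner(table, "gap_penalized").best_config is cfg_small_c

    def test_repeated_run_is_deterministic(self):
        X, y = _separable_data(seed=2)
        folds = stratified_folds(y, k=3, seed=1)
        grid = [
            ModelConfig.make("random_forest", seed=1, n_estimators=20, min_samples_leaf=l)
            for l in (1, 8)
        ]
        a = grid_search(grid, X, y, folds, "gap_penalized", fit_winner=False)
        b = grid_search(grid, X, y, folds, "gap_penalized", fit_winner=False)
        assert a.best_config == b.best_config
        assert a.best_score == pytest.approx(b.best_score)
        for ra, rb in zip(a.table, b.table):
            assert ra["score_validation"] == pytest.approx(rb["score_validation"])

    def test_both_scores_stored_for_every_config(self):
        X, y = _separable_data(seed=3)
        folds = stratified_folds(y, k=3, seed=0)
        grid = [
            ModelConfig.make("random_forest", seed=0, n_estimators=10, min_samples_leaf=l)
            for l in (1, 4)
        ]
        outcome = grid_search(grid, X, y, folds, "validation", fit_winner=False)
        assert len(outcome.table) == 2
        for row in outcome.table:
            assert {"score_validation", "score_gap_penalized", "cv"} <= row.keys()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search([], np.zeros((4, 2)), [0, 1, 0, 1], np.zeros(4, int), "validation")


class TestFitPredict:
    def test_interpolating_model_reaches_training_mcc_one(self):
        X, y = _separable_data(seed=4)
        art = fit_final(
            ModelConfig.make("random_forest", seed=0, n_estimators=50, min_samples_leaf=1),
            X, y,
        )
        labels, _ = predict(art, X)
        assert mcc_from_predictions(y, labels) == pytest.approx(1.0)

    def test_scores_are_probabilities_and_define_labels(self):
        X, y = _separable_data(seed=6)
        art = fit_final(ModelConfig.make("random_forest", seed=0, n_estimators=30), X, y)
        labels, scores = predict(art, X)
        assert ((scores >= 0) & (scores <= 1)).all()
        assert np.array_equal(labels, (scores >= 0.5).astype(int))

    def test_svm_pipeline_scores_are_probabilities(self):
        X, y = _separable_data(seed=7)
        art = fit_final(ModelConfig.make("svm", seed=0, C=1.0), X, y)
        _, scores = predict(art, X)
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_feature_count_mismatch_is_an_error(self):
        X, y = _separable_data(seed=8)
        art = fit_final(ModelConfig.make("random_forest", seed=0, n_estimators=10), X, y)
        with pytest.raises(ValueError, match="feature-count mismatch"):
            predict(art, X[:, :3])

    def test_single_class_training_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            fit_final(ModelConfig.make("random_forest", seed=0), X, np.ones(10, int))

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig.make("svm", C=-1.0)
        with pytest.raises(ValueError):
            ModelConfig.make("random_forest", n_estimators=0)
        with pytest.raises(ValueError):
            ModelConfig.make("gradient_boosting")
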