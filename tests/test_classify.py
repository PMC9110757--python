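"""SVM, grid search, cross-entropy, CNN and gain-ratio tree."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from i5hmcvec import (
    GainRatioTreeClassifier,
    GridSpec,
    bce_loss,
    gain_ratio,
    grid_search,
    predict,
    rbf_kernel,
    train_cnn,
    train_svm,
)
from i5hmcvec.errors import DegenerateLabelsError, InvalidInputError

finite_vec = arrays(
    float,
    4,
    elements=st.floats(min_value=-10, max_value=10, allow_nan=False),
)


class TestRBFKernel:
    def test_zero_distance_gives_one(self):
        v = np.array([1.0, 2.0, 3.0])
        assert rbf_kernel(v, v, gamma=0.5) == 1.0

    def test_gamma_zero_limit(self):
        assert rbf_kernel(np.zeros(3), np.ones(3), gamma=0.0) == 1.0

    def test_unit_distance_closed_form(self):
        assert rbf_kernel(np.array([0.0]), np.array([1.0]), 1.0) == pytest.approx(
            math.exp(-1), abs=1e-9
        )

    def test_dimension_mismatch(self):
        with pytest.raises(InvalidInputError):
            rbf_kernel(np.zeros(3), np.zeros(4), 1.0)

    @settings(deadline=None, derandomize=True)
    @given(a=finite_vec, b=finite_vec, gamma=st.floats(0.01, 5.0))
    def test_symmetric_and_bounded(self, a, b, gamma):
        kab = rbf_kernel(a, b, gamma)
        assert kab == pytest.approx(rbf_kernel(b, a, gamma))
        # mathematically in (0, 1]; 0.0 only via floating-point underflow
        assert 0.0 <= kab <= 1.0

    def test_gram_matrix_positive_semidefinite(self):
        rng = np.random.default_rng(0)
        for gamma in (0.1, 1.0):
            X = rng.normal(size=(12, 5))
            gram = np.array(
                [[rbf_kernel(a, b, gamma) for b in X] for a in X]
            )
            assert np.linalg.eigvalsh(gram).min() >= -1e-8


SEP_X = np.array([[0.0, 0.0], [0.2, 0.1], [3.0, 3.0], [3.2, 2.9]])
SEP_Y = np.array([0, 0, 1, 1])


class TestTrainSVM:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        model = train_svm(SEP_X, SEP_Y, c=10.0, gamma=0.5)
        assert (model.predict(SEP_X) == SEP_Y).all()

    def test_identical_features_give_chance_accuracy(self):
        X = np.ones((8, 3))
        y = np.array([0, 1] * 4)
        model = train_svm(X, y, c=1.0, gamma=0.1)
        assert (model.predict(X) == y).mean() == 0.5

    def test_nonpositive_cost_rejected(self):
        with pytest.raises(InvalidInputError):
            train_svm(SEP_X, SEP_Y, c=0.0, gamma=0.1)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            train_svm(SEP_X, np.ones(4, dtype=int), c=1.0, gamma=0.1)

    def test_scores_invariant_to_sample_order(self):
        model = train_svm(SEP_X, SEP_Y, c=10.0, gamma=0.5)
        rng = np.random.default_rng(0)
        probe = rng.normal(size=(6, 2))
        perm = rng.permutation(6)
        _, s1 = predict(model, probe)
        _, s2 = predict(model, probe[perm])
        assert np.allclose(s1[perm], s2)

    def test_wrong_dimension_rejected(self):
        model = train_svm(SEP_X, SEP_Y)
        with pytest.raises(InvalidInputError):
            model.predict(np.zeros((2, 5)))


class TestGridSearch:
    def test_default_grid_has_11_by_11_cells(self):
        grid = GridSpec()
        assert len(grid.c_values) == 11
        assert len(grid.gamma_values) == 11
        assert grid.c_values[0] == 2.0**-5 and grid.c_values[-1] == 2.0**15
        assert grid.gamma_values[0] == 2.0**-15

    def test_single_cell_grid_returns_that_cell(self):
        grid = GridSpec(c_exponents=[3], gamma_exponents=[-4])
        res = grid_search(SEP_X, SEP_Y, grid, cv_folds=2, seed=0)
        assert res.best_c == 2.0**3
        assert res.best_gamma == 2.0**-4

    def test_best_cell_is_argmax_of_returned_table(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (15, 4)), rng.normal(1.5, 1, (15, 4))])
        y = np.array([0] * 15 + [1] * 15)
        grid = GridSpec(c_exponents=[-1, 3, 7], gamma_exponents=[-7, -4, -1])
        res = grid_search(X, y, grid, cv_folds=3, seed=0)
        assert res.best_score == res.table["mean_score"].max()

    def test_ties_break_to_smaller_c_then_gamma(self):
        X = np.ones((8, 3))  # no signal: every cell scores identically
        y = np.array([0, 1] * 4)
        grid = GridSpec(c_exponents=[-1, 0, 1], gamma_exponents=[-3, -2])
        res = grid_search(X, y, grid, cv_folds=2, seed=0)
        assert res.best_c == 2.0**-1
        assert res.best_gamma == 2.0**-3

    def test_empty_grid_rejected(self):
        with pytest.raises(InvalidInputError):
            GridSpec(c_exponents=[], gamma_exponents=[-3])


class TestBCELoss:
    def test_confident_correct_predictions_near_zero(self):
        y = np.array([1.0, 0.0, 1.0])
        h = np.array([1 - 1e-9, 1e-9, 1 - 1e-9])
        assert bce_loss(y, h) == pytest.approx(0.0, abs=1e-6)

    def test_uninformative_half_gives_ln2(self):
        y = np.array([1.0, 0.0, 1.0, 0.0])
        assert bce_loss(y, np.full(4, 0.5)) == pytest.approx(math.log(2))

    def test_exact_zero_or_one_clipped_to_finite(self):
        loss = bce_loss(np.array([1.0]), np.array([0.0]))
        assert np.isfinite(loss)

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            bce_loss(np.ones(3), np.ones(2) * 0.5)


class TestCNN:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(0, 1, (10, 12)) + 3, rng.normal(0, 1, (10, 12)) - 3]
        )
        y = np.array([1] * 10 + [0] * 10)
        model = train_cnn(X, y, learning_rate=5e-2, epochs=100, seed=0)
        assert (model.predict(X) == y).mean() == 1.0

    def test_untrained_network_sits_near_half(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 12))
        y = np.array([1, 0] * 10)
        model = train_cnn(X, y, epochs=0, seed=0)
        loss = bce_loss(y.astype(float), model.decision_scores(X))
        assert loss == pytest.approx(math.log(2), abs=0.1)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(16, 10))
        y = np.array([0, 1] * 8)
        s1 = train_cnn(X, y, epochs=5, seed=3).decision_scores(X)
        s2 = train_cnn(X, y, epochs=5, seed=3).decision_scores(X)
        assert np.array_equal(s1, s2)


class TestGainRatio:
    def test_perfect_binary_split_of_balanced_data_is_one(self):
        labels = np.array([1, 1, 0, 0])
        feature = np.array([0.0, 0.0, 1.0, 1.0])
        assert gain_ratio(labels, feature, split=0.5) == pytest.approx(1.0)

    def test_label_independent_feature_is_zero(self):
        labels = np.array([1, 0, 1, 0])
        feature = np.array([0.0, 0.0, 1.0, 1.0])
        assert gain_ratio(labels, feature, split=0.5) == 0.0

    def test_degenerate_single_branch_is_zero(self):
        labels = np.array([1, 0, 1, 0])
        feature = np.zeros(4)
        assert gain_ratio(labels, feature, split=0.5) == 0.0

    def test_categorical_groups_accepted(self):
        labels = np.array([1, 1, 0, 0, 1, 0])
        groups = np.array(["a", "a", "b", "b", "a", "b"])
        assert gain_ratio(labels, groups) == pytest.approx(1.0)


class TestGainRatioTree:
    def test_fits_separable_data(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.3, (12, 3)), rng.normal(2, 0.3, (12, 3))])
        y = np.array([0] * 12 + [1] * 12)
        model = GainRatioTreeClassifier(prune_confidence=0.25).fit(X, y)
        assert (model.predict(X) == y).mean() >= 0.9
        labels, scores = predict(model, X)
        assert labels.shape == scores.shape == (24,)
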