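"""MLP internals: forward/backward passes, ADAM, dropout, early stopping,
splitting and sliding-window selection."""

import numpy as np
import pytest

from ramanotype.nn import (
    AdamState,
    MLPClassifier,
    MLPRegressor,
    SplitSpec,
    adam_init,
    adam_step,
    cce_loss,
    dropout_mask,
    hyperparameter_search,
    n_windows,
    sliding_window_selection,
    split_data,
)


def _toy_classifier(rng, n_in=5, hidden=(4,), n_classes=3):
    model = MLPClassifier(hidden_layer_sizes=hidden, random_state=0)
    model.classes_ = np.arange(n_classes)
    model._init_network(n_in, n_classes, rng)
    return model


def _toy_regressor(rng, n_in=5, hidden=(4,)):
    model = MLPRegressor(hidden_layer_sizes=hidden, random_state=0)
    model._init_network(n_in, 1, rng)
    return model


class TestForward:
    def test_probabilities_sum_to_one(self, rng):
        model = _toy_classifier(rng)
        P = model.forward(rng.normal(size=(7, 5)))
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_weights_give_uniform(self, rng):
        model = _toy_classifier(rng, n_classes=7)
        model.weights_ = [np.zeros_like(W) for W in model.weights_]
        model.biases_ = [np.zeros_like(b) for b in model.biases_]
        P = model.forward(rng.normal(size=(3, 5)))
        np.testing.assert_allclose(P, 1.0 / 7.0, atol=1e-12)

    def test_inference_deterministic(self, rng):
        model = _toy_classifier(rng)
        model.dropout = 0.5  # must not be applied outside training
        X = rng.normal(size=(4, 5))
        np.testing.assert_array_equal(model.forward(X), model.forward(X))

    def test_regression_output_nonnegative(self, rng):
        model = _toy_regressor(rng)
        assert (model.forward(rng.normal(size=(20, 5)) * 10) >= 0).all()

    def test_shape_mismatch_rejected(self, rng):
        model = _toy_classifier(rng)
        with pytest.raises(ValueError):
            model.forward(np.ones((2, 9)))


class TestCceLoss:
    def test_perfect_prediction_near_zero(self):
        P = np.eye(3)
        assert cce_loss(P, np.eye(3)) < 1e-10

    def test_uniform_seven_classes_is_ln7(self):
        P = np.full((4, 7), 1.0 / 7.0)
        Y = np.eye(7)[[0, 3, 5, 6]]
        assert cce_loss(P, Y) == pytest.approx(np.log(7.0), abs=1e-12)

    def test_batch_equals_per_sample_loop(self, rng):
        logits = rng.normal(size=(6, 4))
        P = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        Y = np.eye(4)[rng.integers(0, 4, size=6)]
        per_sample = [cce_loss(P[i : i + 1], Y[i : i + 1]) for i in range(6)]
        assert cce_loss(P, Y) == pytest.approx(np.mean(per_sample), abs=1e-12)


class TestBackprop:
    @pytest.mark.parametrize("head", ["classification", "regression"])
    @pytest.mark.parametrize("hidden", [(4,), (6, 5)])
    def test_gradients_match_finite_differences(self, head, hidden):
        rng = np.random.default_rng(3)
        if head == "classification":
            model = _toy_classifier(rng, hidden=hidden)
            Y = np.eye(3)[rng.integers(0, 3, size=8)]
        else:
            model = _toy_regressor(rng, hidden=hidden)
            Y = np.abs(rng.normal(size=8)) + 0.5
        X = rng.normal(size=(8, 5))
        Y2 = Y if Y.ndim == 2 else Y[:, None]
        gW, gb = model.backprop_gradients(X, Y2)
        params = model.weights_ + model.biases_
        grads = gW + gb
        eps = 1e-6
        for p, g in zip(params, grads):
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = p[idx]
                p[idx] = orig + eps
                up = model._loss(model.forward(X), Y2)
                p[idx] = orig - eps
                down = model._loss(model.forward(X), Y2)
                p[idx] = orig
                fd = (up - down) / (2 * eps)
                assert g[idx] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_gradient_zero_at_perfect_fit(self, rng):
        # a regressor that exactly reproduces its targets has zero gradient
        model = _toy_regressor(rng, n_in=2, hidden=(2,))
        model.weights_ = [np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([[1.0], [1.0]])]
        model.biases_ = [np.zeros(2), np.zeros(1)]
        X = np.abs(rng.normal(size=(5, 2)))
        y = X.sum(axis=1)
        gW, gb = model.backprop_gradients(X, y[:, None])
        for g in gW + gb:
            np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_duplicating_batch_leaves_mean_gradient_unchanged(self, rng):
        model = _toy_classifier(rng)
        X = rng.normal(size=(6, 5))
        Y = np.eye(3)[rng.integers(0, 3, size=6)]
        g1W, g1b = model.backprop_gradients(X, Y)
        g2W, g2b = model.backprop_gradients(np.vstack([X, X]), np.vstack([Y, Y]))
        for a, b in zip(g1W + g1b, g2W + g2b):
            np.testing.assert_allclose(a, b, atol=1e-12)


class TestAdam:
    def test_zero_gradient_leaves_params_unchanged(self):
        params = [np.array([1.0, -2.0])]
        state = adam_init(params)
        adam_step(params, [np.zeros(2)], state)
        np.testing.assert_array_equal(params[0], [1.0, -2.0])

    def test_first_step_is_lr_times_sign(self):
        params = [np.array([1.0, 1.0])]
        state = adam_init(params)
        g = np.array([0.5, -0.25])
        adam_step(params, [g], state, lr=1e-3)
        np.testing.assert_allclose(params[0], [1.0 - 1e-3, 1.0 + 1e-3], atol=1e-6)

    def test_trajectory_deterministic(self, rng):
        g_seq = rng.normal(size=(10, 3))

        def run():
            params = [np.zeros(3)]
            state = adam_init(params)
            for g in g_seq:
                adam_step(params, [g.copy()], state)
            return params[0].copy()

        np.testing.assert_array_equal(run(), run())


class TestDropout:
    def test_rate_zero_is_identity(self, rng):
        np.testing.assert_array_equal(dropout_mask((3, 4), 0.0, rng), np.ones((3, 4)))

    def test_expectation_preserved(self):
        rng = np.random.default_rng(0)
        mask = dropout_mask((100_000,), 0.4, rng)
        assert mask.mean() == pytest.approx(1.0, abs=0.01)

    def test_same_seed_same_mask(self):
        a = dropout_mask((5, 5), 0.3, np.random.default_rng(9))
        b = dropout_mask((5, 5), 0.3, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_rate_one_rejected(self, rng):
        with pytest.raises(ValueError):
            dropout_mask((2, 2), 1.0, rng)


class TestTraining:
    def _separable(self, rng, n=40):
        X = np.vstack([rng.normal(size=(n // 2, 4)) - 3, rng.normal(size=(n // 2, 4)) + 3])
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        return X, y

    def test_separable_data_reaches_full_training_accuracy(self, rng):
        X, y = self._separable(rng)
        model = MLPClassifier(hidden_layer_sizes=(8,), max_epochs=300, random_state=1)
        model.fit(X, y)
        assert model.score(X, y) == 1.0

    def test_patience_zero_stops_right_after_best_epoch(self, rng):
        X, y = self._separable(rng)
        model = MLPClassifier(hidden_layer_sizes=(8,), max_epochs=500,
                              patience=0, random_state=1)
        model.fit(X, y, X, y)
        assert (model.stopped_epoch_ == model.best_epoch_ + 1
                or model.stopped_epoch_ == model.max_epochs)

    def test_fixed_seed_reproducible(self, rng):
        X, y = self._separable(rng)
        runs = []
        for _ in range(2):
            m = MLPClassifier(hidden_layer_sizes=(6,), dropout=0.2,
                              max_epochs=50, random_state=7)
            m.fit(X, y)
            runs.append((m.stopped_epoch_, m.history_.copy()))
        assert runs[0][0] == runs[1][0]
        np.testing.assert_array_equal(runs[0][1], runs[1][1])

    def test_restored_weights_achieve_best_validation_loss(self, rng):
        X, y = self._separable(rng, n=30)
        Xv, yv = self._separable(np.random.default_rng(5), n=10)
        model = MLPClassifier(hidden_layer_sizes=(8,), dropout=0.3,
                              max_epochs=120, patience=10, random_state=2)
        model.fit(X, y, Xv, yv)
        val_loss_now = model.test_loss(Xv, yv)
        assert val_loss_now == pytest.approx(model.history_[:, 1].min(), abs=1e-10)


class TestSplitData:
    def test_exact_sizes(self):
        tr, va, te = split_data(100, SplitSpec((0.8, 0.1, 0.1), seed=0))
        assert (len(tr), len(va), len(te)) == (80, 10, 10)
        tr, va, te = split_data(10, SplitSpec((0.6, 0.2, 0.2), seed=0))
        assert (len(tr), len(va), len(te)) == (6, 2, 2)

    def test_union_is_everything_no_duplicates(self):
        parts = split_data(53, SplitSpec((0.7, 0.2, 0.1), seed=3))
        allidx = np.concatenate(parts)
        assert sorted(allidx) == list(range(53))

    def test_stratified_preserves_class_balance(self, rng):
        labels = np.repeat(["a", "b", "c", "d"], 25)
        tr, va, te = split_data(100, SplitSpec((0.8, 0.1, 0.1), seed=1, stratify=True),
                                labels=labels)
        for part, expect in ((tr, 20), (va, 3), (te, 2)):
            counts = np.unique(labels[part], return_counts=True)[1]
            assert counts.min() >= expect

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SplitSpec((0.5, 0.2))


class TestSlidingWindow:
    def test_candidate_count_formula(self):
        assert n_windows(512, 62, 2) == 226
        assert n_windows(62, 62, 2) == 1

    def test_single_window_returned(self, rng):
        X = rng.normal(size=(5, 10))
        start, stop = sliding_window_selection(X, None, lambda Xw, y: 0.0,
                                               window=10, step=2)
        assert (start, stop) == (0, 10)

    def test_lowest_error_window_wins_leftmost_tie(self, rng):
        X = rng.normal(size=(3, 20))
        errors = {0: 1.0, 2: 0.3, 4: 0.3, 6: 0.8, 8: 0.9, 10: 2.0}
        seen = []

        def ev(Xw, y):
            seen.append(None)
            return errors[(len(seen) - 1) * 2]  # evaluator keyed on window start

        start, stop = sliding_window_selection(X, None, ev, window=10, step=2)
        assert (start, stop) == (2, 12)  # 0.3 tie at starts 2 and 4 → leftmost

    def test_window_longer_than_axis_rejected(self, rng):
        with pytest.raises(ValueError):
            sliding_window_selection(rng.normal(size=(2, 5)), None,
                                     lambda *a: 0.0, window=6)


class TestHyperparameterSearch:
    def _tiny_data(self, rng):
        X = np.vstack([rng.normal(size=(12, 6)) - 2, rng.normal(size=(12, 6)) + 2])
        y = np.array(["lo"] * 12 + ["hi"] * 12)
        return X, y

    def test_table_has_one_row_per_trial_and_rank_order(self, rng):
        X, y = self._tiny_data(rng)
        table = hyperparameter_search(X, y, X[:6], y[:6], X[6:12], y[6:12],
                                      n_trials=5, seed=0, max_epochs=40, patience=5)
        assert len(table) == 5
        assert sorted(table["trial"]) == list(range(5))  # ranking is a permutation
        acc = table["accuracy_pct"].to_numpy()
        assert (np.diff(acc) <= 1e-9).all()
        same = acc[:-1] == acc[1:]
        loss_pairs = table["test_loss"].to_numpy()
        assert ((np.diff(loss_pairs) >= -1e-12) | ~same).all()

    def test_topology_string_format(self, rng):
        model = MLPClassifier(hidden_layer_sizes=(242,), random_state=0)
        model.classes_ = np.arange(7)
        model._init_network(60, 7, rng)
        assert model.topology_ == "60-242-7"
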