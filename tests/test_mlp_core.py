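import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from luminet.dataset import ExpressionDataset
from luminet.exceptions import ConfigError, DataError, ShapeError, SplitError
from luminet.mlp_core import (
    DataSplit,
    TrainedMLP,
    TrainingConfig,
    evaluate_mse,
    make_mccv_splits,
    predict,
    sample_gradients,
    scale_to_unit,
    train_mlp,
)


def _dataset(values, labels=None):
    values = np.asarray(values, dtype=float)
    return ExpressionDataset(
        values=values,
        probe_ids=[f"P{i}" for i in range(values.shape[0])],
        sample_ids=[f"S{j}" for j in range(values.shape[1])],
        labels=labels,
    )


class TestScaleToUnit:
    def test_linear_map(self):
        out = scale_to_unit(_dataset([[2, 4, 6]]))
        assert np.allclose(out.values, [[0, 0.5, 1]])

    def test_constant_probe_maps_to_half(self):
        out = scale_to_unit(_dataset([[3, 3, 3]]))
        assert np.allclose(out.values, 0.5)

    def test_idempotent_on_unit_extremes(self):
        vals = np.array([[0.0, 0.3, 1.0], [0.0, 1.0, 0.6]])
        out = scale_to_unit(_dataset(vals))
        assert np.allclose(out.values, vals)

    def test_nonfinite_names_probe(self):
        with pytest.raises(DataError, match="P1"):
            scale_to_unit(_dataset([[1, 2, 3], [1, np.nan, 3]]))

    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=20,
        )
    )
    def test_range_property(self, row):
        out = scale_to_unit(_dataset([row])).values
        assert out.min() >= 0 and out.max() <= 1
        if len(set(row)) > 1:
            assert out.min() == 0 and out.max() == 1


class TestMCCVSplits:
    def test_exact_division(self):
        s = make_mccv_splits(10, 1, seed=0)[0]
        assert (len(s.train_idx), len(s.test_idx), len(s.validation_idx)) == (6, 2, 2)

    def test_remainder_goes_to_train(self):
        s = make_mccv_splits(278, 1, seed=0)[0]
        sizes = (len(s.train_idx), len(s.test_idx), len(s.validation_idx))
        assert sizes == (168, 55, 55)
        assert sum(sizes) == 278

    def test_partition_contract(self):
        for s in make_mccv_splits(53, 5, seed=3):
            allidx = np.concatenate([s.train_idx, s.test_idx, s.validation_idx])
            assert sorted(allidx) == list(range(53))

    def test_reproducible_and_varying(self):
        a = make_mccv_splits(40, 3, seed=9)
        b = make_mccv_splits(40, 3, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.train_idx, y.train_idx)
        assert not np.array_equal(a[0].train_idx, a[1].train_idx)

    def test_too_few_samples(self):
        with pytest.raises(SplitError):
            make_mccv_splits(4, 1)

    def test_overlapping_split_rejected(self):
        with pytest.raises(SplitError):
            DataSplit(train_idx=[0, 1], test_idx=[1, 2], validation_idx=[3])


class TestTraining:
    def test_separable_target_reaches_low_mse(self, one_split):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 200)
        y = (x > 0.5).astype(float)
        cfg = TrainingConfig(max_epochs=500, patience_epochs=200, seed=0)
        model = train_mlp(x[None, :], y, one_split, cfg)
        assert model.best_test_mse < 0.05

    def test_noise_target_hits_irreducible_error(self, one_split):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 200)
        y = rng.uniform(0, 1, 200)
        v = float(np.var(y[one_split.test_idx]))
        cfg = TrainingConfig(max_epochs=300, patience_epochs=150, seed=1)
        model = train_mlp(x[None, :], y, one_split, cfg)
        assert abs(model.best_test_mse - v) <= 0.2 * v

    def test_zero_patience_stops_after_first_epoch(self, one_split):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 200)
        y = (x > 0.5).astype(float)
        cfg = TrainingConfig(max_epochs=100, patience_epochs=0, seed=0)
        model = train_mlp(x[None, :], y, one_split, cfg)
        assert model.epochs_run == 1

    def test_snapshot_mse_matches_returned_weights(self, one_split):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (3, 200))
        y = (X[0] + 0.3 * X[1] > 0.6).astype(float)
        cfg = TrainingConfig(max_epochs=150, patience_epochs=75, seed=4)
        model = train_mlp(X, y, one_split, cfg)
        recomputed = evaluate_mse(
            model, X[:, one_split.test_idx], y[one_split.test_idx]
        )
        assert recomputed == pytest.approx(model.best_test_mse, abs=1e-12)
        assert model.snapshot_epoch <= model.epochs_run <= cfg.max_epochs

    def test_seed_determinism(self, one_split):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 200)
        y = (x > 0.4).astype(float)
        cfg = TrainingConfig(max_epochs=50, patience_epochs=25, seed=11)
        m1 = train_mlp(x[None, :], y, one_split, cfg)
        m2 = train_mlp(x[None, :], y, one_split, cfg)
        assert np.array_equal(m1.w_in_hidden, m2.w_in_hidden)
        assert m1.best_test_mse == m2.best_test_mse

    def test_validation_never_influences_result(self, one_split):
        """Shuffling validation targets changes only the reported held-out MSE."""
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 200)
        y = (x > 0.5).astype(float)
        cfg = TrainingConfig(max_epochs=60, patience_epochs=30, seed=6)
        m1 = train_mlp(x[None, :], y, one_split, cfg)
        y2 = y.copy()
        y2[one_split.validation_idx] = rng.permutation(y2[one_split.validation_idx])
        m2 = train_mlp(x[None, :], y2, one_split, cfg)
        assert np.array_equal(m1.w_in_hidden, m2.w_in_hidden)
        assert m1.best_test_mse == m2.best_test_mse

    def test_empty_subset_rejected(self):
        x = np.linspace(0, 1, 10)[None, :]
        y = np.zeros(10)
        split = DataSplit(train_idx=np.arange(8), test_idx=[], validation_idx=[8, 9])
        with pytest.raises(SplitError):
            train_mlp(x, y, split, TrainingConfig(seed=0))

    def test_unscaled_input_rejected(self, one_split):
        x = np.linspace(-3, 3, 200)[None, :]
        with pytest.raises(DataError):
            train_mlp(x, np.zeros(200), one_split, TrainingConfig(seed=0))

    def test_invalid_hyperparameters(self):
        with pytest.raises(ConfigError):
            TrainingConfig(momentum=1.0)
        with pytest.raises(ConfigError):
            TrainingConfig(learning_rate=0)
        with pytest.raises(ConfigError):
            TrainingConfig(patience_epochs=5000, max_epochs=3000)


class TestGradients:
    def test_analytic_matches_finite_difference(self, rng):
        """Backprop gradients agree with central differences to <1e-4 relative."""
        W1 = rng.normal(0, 0.5, (3, 2))
        b1 = rng.normal(0, 0.5, 2)
        w2 = rng.normal(0, 0.5, 2)
        b2 = 0.2
        X = rng.uniform(0, 1, (3, 3))
        ys = [0.0, 1.0, 0.3]

        def loss(W1, b1, w2, b2, x, y):
            h = 1 / (1 + np.exp(-(x @ W1 + b1)))
            o = 1 / (1 + np.exp(-(h @ w2 + b2)))
            return (o - y) ** 2

        eps = 1e-6
        for x, y in zip(X.T, ys):
            dW1, db1, dw2, db2 = sample_gradients(W1, b1, w2, b2, x, y)
            for idx in np.ndindex(W1.shape):
                Wp, Wm = W1.copy(), W1.copy()
                Wp[idx] += eps
                Wm[idx] -= eps
                fd = (loss(Wp, b1, w2, b2, x, y) - loss(Wm, b1, w2, b2, x, y)) / (2 * eps)
                assert dW1[idx] == pytest.approx(fd, rel=1e-4, abs=1e-10)
            fd = (loss(W1, b1, w2, b2 + eps, x, y) - loss(W1, b1, w2, b2 - eps, x, y)) / (2 * eps)
            assert db2 == pytest.approx(fd, rel=1e-4, abs=1e-10)

    def test_zero_momentum_equals_plain_sgd_one_epoch(self):
        """At momentum 0 one epoch of the trainer equals hand-rolled online SGD."""
        rng = np.random.default_rng(42)
        n = 20
        x = rng.uniform(0, 1, n)
        y = (x > 0.5).astype(float)
        split = DataSplit(
            train_idx=np.arange(12), test_idx=np.arange(12, 16),
            validation_idx=np.arange(16, 20),
        )
        cfg = TrainingConfig(
            max_epochs=1, patience_epochs=0, momentum=0.0, learning_rate=0.1, seed=5
        )
        model = train_mlp(x[None, :], y, split, cfg)

        # independent replay: same init and shuffling stream as the trainer
        r = np.random.default_rng(5)
        W1 = r.uniform(-0.5, 0.5, (1, 2))
        b1 = r.uniform(-0.5, 0.5, 2)
        w2 = r.uniform(-0.5, 0.5, 2)
        b2 = float(r.uniform(-0.5, 0.5))
        order = r.permutation(12)
        for s in order:
            xi = x[split.train_idx[s]]
            dW1, db1, dw2, db2 = sample_gradients(W1, b1, w2, b2, np.array([xi]), y[split.train_idx[s]])
            b2 -= 0.1 * db2
            w2 = w2 - 0.1 * dw2
            b1 = b1 - 0.1 * db1
            W1 = W1 - 0.1 * dW1
        assert np.allclose(model.w_in_hidden, W1, atol=1e-12)
        assert np.allclose(model.w_hidden_out, w2, atol=1e-12)
        assert model.b_out == pytest.approx(b2, abs=1e-12)


class TestPredict:
    def test_all_zero_weights_output_half(self):
        model = TrainedMLP(
            w_in_hidden=np.zeros((4, 2)), b_hidden=np.zeros(2),
            w_hidden_out=np.zeros(2), b_out=0.0,
            best_test_mse=0.0, epochs_run=1, snapshot_epoch=1,
        )
        out = predict(model, np.random.default_rng(0).uniform(0, 1, (4, 7)))
        assert np.allclose(out, 0.5)

    def test_outputs_strictly_in_unit_interval(self, rng):
        model = TrainedMLP(
            w_in_hidden=rng.normal(0, 3, (5, 2)), b_hidden=rng.normal(0, 3, 2),
            w_hidden_out=rng.normal(0, 3, 2), b_out=1.0,
            best_test_mse=0.0, epochs_run=1, snapshot_epoch=1,
        )
        out = predict(model, rng.uniform(0, 1, (5, 50)))
        assert out.min() > 0 and out.max() < 1

    def test_monotone_after_training_identity(self, one_split):
        x = np.linspace(0, 1, 200)
        cfg = TrainingConfig(max_epochs=400, patience_epochs=200, seed=1)
        model = train_mlp(x[None, :], x, one_split, cfg)
        grid = np.linspace(0, 1, 50)
        out = predict(model, grid[None, :])
        assert (np.diff(out) > -1e-9).all()

    def test_shape_mismatch(self):
        model = TrainedMLP(
            w_in_hidden=np.zeros((4, 2)), b_hidden=np.zeros(2),
            w_hidden_out=np.zeros(2), b_out=0.0,
            best_test_mse=0.0, epochs_run=1, snapshot_epoch=1,
        )
        with pytest.raises(ShapeError):
            predict(model, np.zeros((3, 5)))


def test_trained_mlp_json_round_trip(one_split):
    rng = np.random.default_rng(6)
    x = rng.uniform(0, 1, 200)
    y = (x > 0.5).astype(float)
    model = train_mlp(
        x[None, :], y, one_split, TrainingConfig(max_epochs=20, patience_epochs=10, seed=2)
    )
    clone = TrainedMLP.from_json(model.to_json())
    assert np.array_equal(clone.w_in_hidden, model.w_in_hidden)
    assert clone.best_test_mse == model.best_test_mse
    assert clone.validation_mse == model.validation_mse
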