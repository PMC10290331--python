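"""Architecture contracts: shapes, parameter counts, training semantics."""

import numpy as np
import pytest
from sklearn.base import clone

from kinemg.models import (
    ArchitectureSpec,
    CNNRegressor,
    FNNRegressor,
    FNNSeqRegressor,
    RNNRegressor,
    RNNSeqRegressor,
    TrainConfig,
    build,
    load_predictor,
    make_training_views,
    save_predictor,
    transfer_weights,
)
from kinemg.preprocess import SequencePair


def _pairs(rng, n=2, T=457, F=18):
    out = []
    for i in range(n):
        out.append(SequencePair(motion=rng.uniform(-1, 1, (T, F)),
                                emg=rng.uniform(0, 1, (T, 8)),
                                subject=1, task=0, repetition=i))
    return out


def _lstm_params(f, h):
    return 4 * (f * h + h * h + h)


def _dense_params(f, h):
    return f * h + h


def _conv_params(k, cin, cout):
    return k * cin * cout + cout


class TestArchitectureDefaults:
    def test_rnn_default_stack_and_count(self):
        est = RNNRegressor()
        est.net_ = est._build_net(18, np.random.default_rng(0))
        expected = (_lstm_params(18, 256) + _lstm_params(256, 128)
                    + _lstm_params(128, 64) + _dense_params(64, 8))
        assert est.n_parameters_ == expected
        assert est.units == (256, 128, 64)

    def test_fnn_default_stack_and_count(self):
        est = FNNRegressor()
        est.net_ = est._build_net(18, np.random.default_rng(0))
        expected = (_dense_params(18, 512) + _dense_params(512, 256)
                    + _dense_params(256, 128) + _dense_params(128, 8))
        assert est.n_parameters_ == expected

    def test_cnn_default_stack_and_count(self):
        est = CNNRegressor()
        est.net_ = est._build_net(18, np.random.default_rng(0))
        filters, kernels = (128, 128, 128, 128, 64), (32, 8, 8, 4, 4)
        assert est.filters == filters and est.kernel_sizes == kernels
        expected, width = 0, 18
        for f, k in zip(filters, kernels):
            expected += _conv_params(k, width, f)
            width = f
        expected += _dense_params(64, 8)
        assert est.n_parameters_ == expected

    def test_build_factory_and_unknown_kind(self):
        spec = ArchitectureSpec(kind="FNNseq", input_width=18)
        est = build(spec, TrainConfig(seed=3))
        assert isinstance(est, FNNSeqRegressor)
        assert est.random_state == 3
        with pytest.raises(ValueError, match="unknown architecture"):
            ArchitectureSpec(kind="GRU", input_width=18)


class TestTrainingViews:
    def test_fnn_flat_rows(self, rng):
        X, y = make_training_views(_pairs(rng), "FNN")
        assert X.shape == (914, 18)       # 2 sequences x 457 frames
        assert y.shape == (914, 8)

    def test_fnnseq_lag_width(self, rng):
        X, _ = make_training_views(_pairs(rng), "FNNseq")
        assert X.shape[1] == 18 * 7       # current frame + 6 lags

    def test_fnnseq_history_padding_replicates_frame0(self, rng):
        pair = _pairs(rng, n=1)[0]
        X, _ = make_training_views([pair], "FNNseq")
        # at frame 0 every lagged block equals frame 0 itself
        assert np.allclose(X[0].reshape(7, 18), pair.motion[0])

    def test_rnnseq_one_subsequence_per_frame(self, rng):
        X, y = make_training_views(_pairs(rng, n=1), "RNNseq")
        assert X.shape == (457, 21, 18)   # 20 warm-up frames + 1 target frame
        assert y.shape == (457, 8)

    def test_mixed_feature_configs_rejected(self, rng):
        a, b = _pairs(rng)
        b.feature_config = "EEF"
        with pytest.raises(ValueError, match="mixed"):
            make_training_views([a, b], "FNN")


class TestTraining:
    def test_noiseless_linear_map_learned_by_fnn(self, rng):
        X = rng.uniform(-1, 1, (4, 457, 6))
        W = rng.uniform(-0.5, 0.5, (6, 8))
        y = X @ W
        est = FNNRegressor(hidden=(32, 16), dropout=0.0, random_state=0,
                           max_epochs=100)
        est.fit(X[:3], y[:3])
        assert est.history_["train_loss"][-1] < 1e-3

    def test_early_stopping_bounds_completed_epochs(self, rng):
        """Training never runs more than patience epochs past the best one
        when the validation loss deteriorates (exact patience semantics are
        unit-tested on the training loop itself)."""
        X = rng.uniform(-1, 1, (3, 100, 4))
        y = X @ rng.uniform(-0.5, 0.5, (4, 8))
        est = FNNRegressor(hidden=(16,), dropout=0.0, random_state=0,
                           max_epochs=50, patience=5)
        est.fit(X[:2], y[:2], validation_data=(X[2:], -y[2:]))
        assert est.n_epochs_ <= est.best_epoch_ + 5
        assert est.n_epochs_ < 50

    def test_same_seed_reproduces_training_log(self, rng):
        X = rng.uniform(-1, 1, (4, 60, 4))
        y = rng.uniform(0, 1, (4, 60, 8))
        kw = dict(units=(8,), random_state=5, max_epochs=3)
        h1 = RNNRegressor(**kw).fit(X, y).history_
        h2 = RNNRegressor(**kw).fit(X, y).history_
        assert h1["train_loss"] == h2["train_loss"]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            FNNRegressor().fit(np.empty((0, 10, 4)), np.empty((0, 10, 8)))

    def test_validation_loss_matches_independent_mse(self, rng):
        """The reported best-epoch validation loss is exactly the MSE of the
        restored model's predictions."""
        from kinemg.metrics import mse as mse_metric
        X = rng.uniform(-1, 1, (4, 80, 4))
        y = X @ rng.uniform(-0.5, 0.5, (4, 8))
        est = FNNRegressor(hidden=(16,), dropout=0.0, random_state=0, max_epochs=8)
        est.fit(X[:3], y[:3], validation_data=(X[3:], y[3:]))
        pred = est.predict(X[3:])
        best = est.history_["val_loss"][est.best_epoch_ - 1]
        assert mse_metric(y[3:].ravel(), pred.ravel()) == pytest.approx(best, abs=1e-6)

    def test_capacity_ordering_logged(self, rng):
        """Soft check: at equal small budget the RNN's validation MSE is
        expected at or below the FNN's (logged, not asserted)."""
        X = rng.uniform(-1, 1, (6, 60, 6))
        y = np.clip(np.cumsum(X @ rng.uniform(-0.2, 0.2, (6, 8)), axis=1) * 0.05
                    + 0.3, 0, 1)
        val = (X[4:], y[4:])
        rnn = RNNRegressor(units=(16, 8), random_state=0, max_epochs=10,
                           batch_size=2).fit(X[:4], y[:4], validation_data=val)
        fnn = FNNRegressor(hidden=(32, 16), random_state=0, max_epochs=10
                           ).fit(X[:4], y[:4], validation_data=val)
        rnn_val = min(rnn.history_["val_loss"])
        fnn_val = min(fnn.history_["val_loss"])
        print(f"capacity ordering (soft): RNN val MSE {rnn_val:.5f} "
              f"vs FNN val MSE {fnn_val:.5f}")
        assert np.isfinite(rnn_val) and np.isfinite(fnn_val)


class TestPrediction:
    @pytest.mark.parametrize("cls,kw", [
        (RNNRegressor, dict(units=(8,))),
        (RNNSeqRegressor, dict(units=(8,))),
        (FNNRegressor, dict(hidden=(16,))),
        (FNNSeqRegressor, dict(hidden=(16,))),
        (CNNRegressor, dict(filters=(8, 8), kernel_sizes=(5, 3))),
    ])
    def test_output_shape_and_finiteness(self, cls, kw, rng):
        X = rng.uniform(-1, 1, (3, 60, 6))
        y = rng.uniform(0, 1, (3, 60, 8))
        est = cls(random_state=0, max_epochs=1, **kw).fit(X, y)
        pred = est.predict(X)
        assert pred.shape == (3, 60, 8)
        assert np.all(np.isfinite(pred))

    def test_fnn_constant_input_gives_constant_prediction(self, rng):
        X = rng.uniform(-1, 1, (2, 50, 6))
        y = rng.uniform(0, 1, (2, 50, 8))
        est = FNNRegressor(hidden=(16,), random_state=0, max_epochs=1).fit(X, y)
        rest = np.tile(np.full(6, 0.2), (1, 50, 1))
        pred = est.predict(rest)
        assert np.abs(pred - pred[:, :1]).max() < 1e-12

    def test_width_mismatch_rejected(self, rng):
        X = rng.uniform(-1, 1, (2, 50, 6))
        y = rng.uniform(0, 1, (2, 50, 8))
        est = FNNRegressor(hidden=(8,), random_state=0, max_epochs=1).fit(X, y)
        with pytest.raises(ValueError, match="width"):
            est.predict(rng.uniform(-1, 1, (2, 50, 7)))

    def test_warmup_prediction_matches_stateful_twin(self):
        """Single-layer case: the sub-sequence model with 20 warm-up frames
        agrees with a weight-identical stateful LSTM after frame 20."""
        rng = np.random.default_rng(0)
        T, F, H = 120, 6, 16
        X = rng.uniform(-1, 1, (1, T, F))
        rseq = RNNSeqRegressor(units=(H,), dropout=0.0)
        rseq.net_ = rseq._build_net(F, np.random.default_rng(1))
        rseq.n_features_in_ = F
        # moderate weight scale so the state memory fits inside the warm-up
        weights = [w * 0.2 if w.ndim == 2 else w for w in rseq.net_.get_weights()]
        rseq.net_.set_weights(weights)
        rnn = RNNRegressor(units=(H,), dropout=0.0)
        rnn.net_ = rnn._build_net(F, np.random.default_rng(2))
        rnn.n_features_in_ = F
        rnn.net_.set_weights(weights)
        diff = np.abs(rseq.predict(X) - rnn.predict(X))[0]
        assert diff[20:].max() < 1e-4


class TestTransferAndPersistence:
    def _fitted(self, rng, **kw):
        X = rng.uniform(-1, 1, (3, 60, 6))
        y = rng.uniform(0, 1, (3, 60, 8))
        est = RNNRegressor(units=(8,), random_state=1, max_epochs=2, **kw).fit(X, y)
        return est, X, y

    def test_transfer_copies_weights_exactly(self, rng):
        est, X, _ = self._fitted(rng)
        ft = transfer_weights(est)
        assert ft.learning_rate == pytest.approx(1e-4)
        assert np.allclose(ft.predict(X), est.predict(X))

    def test_transfer_then_training_changes_weights(self, rng):
        est, X, y = self._fitted(rng)
        ft = transfer_weights(est)
        ft.set_params(max_epochs=1)
        ft.fit(X, y)
        before = est.net_.get_weights()
        after = ft.net_.get_weights()
        assert any(not np.array_equal(a, b) for a, b in zip(before, after))

    def test_serialization_round_trip_preserves_predictions(self, rng, tmp_path):
        est, X, _ = self._fitted(rng)
        save_predictor(est, tmp_path / "model")
        loaded = load_predictor(tmp_path / "model")
        assert np.array_equal(loaded.predict(X), est.predict(X))

    def test_sklearn_clone_contract(self):
        est = RNNSeqRegressor(units=(8, 4), warmup_len=10, random_state=7)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
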