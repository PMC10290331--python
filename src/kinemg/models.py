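"""Kinematics -> EMG-envelope regressors.

Five architectures, all mapping a motion-feature sequence (457 frames x
n_features) to the 8-channel envelope sequence, trained with Adam on an MSE
loss with early stopping (patience 5) and input dropout:

* :class:`RNNRegressor` — three stacked LSTM layers (256/128/64) with a
  time-distributed linear output; stateful, i.e. hidden/cell states carry
  over between consecutive sequences of one ordered pass (benign because
  every sequence starts and ends at rest) and reset between epochs.
* :class:`RNNSeqRegressor` — the same LSTM stack trained on overlapping
  21-frame sub-sequences: 20 warm-up frames restore the recurrent state
  from scratch, the loss applies to the final frame only.  Suitable for
  online generation.
* :class:`FNNRegressor` — frame-wise dense network (512/256/128, ReLU).
* :class:`FNNSeqRegressor` — dense network whose input is augmented with
  lagged frames at lags {1, 2, 4, 8, 16, 32} (history before frame 0 is
  replicated from the rest-state frame 0).
* :class:`CNNRegressor` — five 1-D convolutions over time
  (128/128/128/128/64 filters, kernels 32/8/8/4/4, 'same' padding, ReLU)
  with a frame-wise linear output.

All estimators follow scikit-learn conventions (``get_params`` /
``set_params``, fitted attributes with trailing underscores) but accept 3-D
``X`` of shape (n_sequences, n_frames, n_features) and ``y`` of shape
(n_sequences, n_frames, 8).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.exceptions import NotFittedError

from . import _nn
from .preprocess import SequencePair

__all__ = [
    "ArchitectureSpec",
    "TrainConfig",
    "ARCHITECTURES",
    "DEFAULT_LAGS",
    "BaseEmgRegressor",
    "RNNRegressor",
    "RNNSeqRegressor",
    "FNNRegressor",
    "FNNSeqRegressor",
    "CNNRegressor",
    "build",
    "make_training_views",
    "transfer_weights",
    "save_predictor",
    "load_predictor",
]

ARCHITECTURES = ("RNN", "RNNseq", "FNN", "FNNseq", "CNN")

#: FNNseq history lags (frames), powers of two capped at 32
DEFAULT_LAGS = (1, 2, 4, 8, 16, 32)

N_OUTPUTS = 8


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of one predictor architecture."""

    kind: str
    input_width: int
    output_width: int = N_OUTPUTS
    units: tuple[int, ...] = (256, 128, 64)            # LSTM stack (RNN/RNNseq)
    hidden: tuple[int, ...] = (512, 256, 128)          # dense stack (FNN/FNNseq)
    filters: tuple[int, ...] = (128, 128, 128, 128, 64)
    kernel_sizes: tuple[int, ...] = (32, 8, 8, 4, 4)
    dropout: float = 0.1
    lags: tuple[int, ...] = DEFAULT_LAGS               # FNNseq only
    warmup_len: int = 20                               # RNNseq only

    def __post_init__(self):
        if self.kind not in ARCHITECTURES:
            raise ValueError(f"unknown architecture kind {self.kind!r}")
        if self.output_width != N_OUTPUTS:
            raise ValueError(f"output width must be {N_OUTPUTS}")
        for widths in (self.units, self.hidden, self.filters):
            if any(w < 1 for w in widths):
                raise ValueError("all layer widths must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings shared by all architectures."""

    learning_rate: float = 1e-3
    batch_size: int | None = None   # architecture default: 128 rows (FNN), 16 sequences
    max_epochs: int = 100
    patience: int = 5
    seed: int = 0


def _lag_augment(seq: np.ndarray, lags: tuple[int, ...]) -> np.ndarray:
    """Append lagged copies of each frame; pre-history replicates frame 0."""
    cols = [seq]
    for lag in lags:
        shifted = np.vstack([np.tile(seq[0], (min(lag, len(seq)), 1)), seq[:-lag]])
        cols.append(shifted[:len(seq)])
    return np.hstack(cols)


def _subsequence_views(seq: np.ndarray, target: np.ndarray | None, warmup: int):
    """Overlapping (warmup+1)-frame windows, one per frame of the sequence."""
    T = seq.shape[0]
    padded = np.vstack([np.tile(seq[0], (warmup, 1)), seq])
    win = np.lib.stride_tricks.sliding_window_view(padded, warmup + 1, axis=0)
    x = np.ascontiguousarray(win.transpose(0, 2, 1))  # (T, warmup+1, F)
    y = None if target is None else target.copy()
    return x, y


def make_training_views(pairs: list[SequencePair], kind: str):
    """Turn SequencePairs into the model-ready tensors of one architecture.

    FNN -> flat (frames, features) rows; FNNseq -> rows with lag-augmented
    features; RNN/CNN -> whole (n_seq, frames, features) sequences; RNNseq
    -> overlapping warm-up sub-sequences with final-frame targets.
    """
    if kind not in ARCHITECTURES:
        raise ValueError(f"unknown architecture kind {kind!r}")
    if not pairs:
        raise ValueError("no sequence pairs supplied")
    configs = {p.feature_config for p in pairs}
    if len(configs) > 1:
        raise ValueError(f"mixed feature configs in one view: {sorted(configs)}")
    X = np.stack([p.motion for p in pairs])
    y = np.stack([p.emg for p in pairs])
    return _views_from_arrays(X, y, kind)


def _views_from_arrays(X: np.ndarray, y: np.ndarray | None, kind: str,
                       lags: tuple[int, ...] = DEFAULT_LAGS, warmup: int = 20):
    if kind == "FNN":
        Xv = X.reshape(-1, X.shape[-1])
        yv = None if y is None else y.reshape(-1, y.shape[-1])
    elif kind == "FNNseq":
        Xv = np.vstack([_lag_augment(seq, lags) for seq in X])
        yv = None if y is None else y.reshape(-1, y.shape[-1])
    elif kind in ("RNN", "CNN"):
        Xv, yv = X, y
    else:  # RNNseq
        xs, ys = [], []
        for i, seq in enumerate(X):
            xv, yv_one = _subsequence_views(seq, None if y is None else y[i], warmup)
            xs.append(xv)
            if yv_one is not None:
                ys.append(yv_one)
        Xv = np.vstack(xs)
        yv = np.vstack(ys) if ys else None
    return Xv, yv


class BaseEmgRegressor(RegressorMixin, BaseEstimator):
    """Shared fit/predict machinery; subclasses define the layer stack."""

    kind: str = ""

    def __init__(self, dropout=0.1, learning_rate=1e-3, batch_size=None,
                 max_epochs=100, patience=5, random_state=None, warm_start=False):
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.random_state = random_state
        self.warm_start = warm_start

    # -- subclass hooks ----------------------------------------------------
    def _build_net(self, n_features: int, rng) -> _nn.Sequential:
        raise NotImplementedError

    def _default_batch_size(self) -> int:
        return 16

    # -- shared ------------------------------------------------------------
    def _validate_X(self, X, fitted: bool) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_sequences, n_frames, n_features)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if fitted and X.shape[-1] != self.n_features_in_:
            raise ValueError(f"input width {X.shape[-1]} does not match the "
                             f"fitted width {self.n_features_in_}")
        return X

    def fit(self, X, y, validation_data=None):
        """Train on sequences, early-stopping on the validation loss.

        ``validation_data`` is an optional ``(X_val, y_val)`` tuple; without
        it the model trains for the full epoch budget.
        """
        X = self._validate_X(X, fitted=False)
        y = np.asarray(y, dtype=float)
        if y.shape[:2] != X.shape[:2] or y.shape[-1] != N_OUTPUTS:
            raise ValueError(f"y must be (n_sequences, n_frames, {N_OUTPUTS})")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(self.random_state)
        if not (self.warm_start and hasattr(self, "net_")):
            self.net_ = self._build_net(X.shape[-1], rng)
        self.n_features_in_ = X.shape[-1]
        Xv, yv = self._views(X, y)
        val_fn = None
        if validation_data is not None:
            Xval = self._validate_X(validation_data[0], fitted=True)
            yval = np.asarray(validation_data[1], dtype=float)
            Xvv, yvv = self._views(Xval, yval)
            val_fn = lambda: _nn.mse_loss(self._forward_eval(Xvv), yvv)[0]
        optimizer = _nn.Adam(self.net_.params, lr=self.learning_rate)
        batch = self.batch_size or self._default_batch_size()
        history = _nn.fit_loop(self.net_, optimizer,
                               self._batch_iter(Xv, yv, batch, rng),
                               val_fn, self.max_epochs, self.patience)
        self.history_ = history
        self.best_epoch_ = history["best_epoch"]
        self.n_epochs_ = len(history["train_loss"])
        return self

    def _views(self, X, y):
        return _views_from_arrays(X, y, self.kind)

    def _batch_iter(self, Xv, yv, batch, rng):
        shuffle = self._shuffle_batches()

        def iterate(epoch):
            n = Xv.shape[0]
            order = rng.permutation(n) if shuffle else np.arange(n)
            for start in range(0, n, batch):
                sel = order[start:start + batch]
                yield Xv[sel], yv[sel]

        return iterate

    def _shuffle_batches(self) -> bool:
        return True

    def _forward_eval(self, Xv, batch: int = 64) -> np.ndarray:
        """Stateless forward pass in evaluation mode (dropout off)."""
        outs = [self.net_.forward(Xv[i:i + batch], training=False)
                for i in range(0, Xv.shape[0], batch)]
        return np.vstack(outs) if outs[0].ndim == 2 else np.concatenate(outs, axis=0)

    def predict(self, X) -> np.ndarray:
        """Predict the 8-channel envelope, (n_sequences, n_frames, 8)."""
        if not hasattr(self, "net_"):
            raise NotFittedError(f"{type(self).__name__} is not fitted")
        X = self._validate_X(X, fitted=True)
        n_seq, T, _ = X.shape
        Xv, _ = self._views(X, None)
        self.net_.reset_states()
        out = self._forward_eval(Xv)
        return out.reshape(n_seq, T, N_OUTPUTS)

    def reset_states(self):
        if hasattr(self, "net_"):
            self.net_.reset_states()

    @property
    def n_parameters_(self) -> int:
        if not hasattr(self, "net_"):
            raise NotFittedError("fit or initialize the network first")
        return self.net_.n_parameters

    def score(self, X, y):
        """Negative MSE (sklearn convention: greater is better)."""
        pred = self.predict(X)
        return -float(np.mean((np.asarray(y, float) - pred) ** 2))


class FNNRegressor(BaseEmgRegressor):
    """Frame-wise dense network, hidden widths 512/256/128."""

    kind = "FNN"

    def __init__(self, hidden=(512, 256, 128), dropout=0.1, learning_rate=1e-3,
                 batch_size=None, max_epochs=100, patience=5, random_state=None,
                 warm_start=False):
        super().__init__(dropout, learning_rate, batch_size, max_epochs,
                         patience, random_state, warm_start)
        self.hidden = hidden

    def _default_batch_size(self):
        return 128

    def _build_net(self, n_features, rng):
        layers: list[_nn.Layer] = [_nn.Dropout(self.dropout, rng)]
        width = self._input_width(n_features)
        for h in self.hidden:
            layers += [_nn.Dense(width, h, rng), _nn.ReLU()]
            width = h
        layers.append(_nn.Dense(width, N_OUTPUTS, rng))
        return _nn.Sequential(layers)

    def _input_width(self, n_features):
        return n_features


class FNNSeqRegressor(FNNRegressor):
    """Dense network fed with lagged history frames at lags 1,2,4,8,16,32."""

    kind = "FNNseq"

    def __init__(self, hidden=(512, 256, 128), lags=DEFAULT_LAGS, dropout=0.1,
                 learning_rate=1e-3, batch_size=None, max_epochs=100, patience=5,
                 random_state=None, warm_start=False):
        super().__init__(hidden, dropout, learning_rate, batch_size, max_epochs,
                         patience, random_state, warm_start)
        self.lags = lags

    def _views(self, X, y):
        return _views_from_arrays(X, y, "FNNseq", lags=tuple(self.lags))

    def _input_width(self, n_features):
        return n_features * (len(self.lags) + 1)


class RNNRegressor(BaseEmgRegressor):
    """Stateful stacked-LSTM sequence model with time-distributed output."""

    kind = "RNN"

    def __init__(self, units=(256, 128, 64), dropout=0.1, learning_rate=1e-3,
                 batch_size=None, max_epochs=100, patience=5, random_state=None,
                 warm_start=False):
        super().__init__(dropout, learning_rate, batch_size, max_epochs,
                         patience, random_state, warm_start)
        self.units = units

    def _build_net(self, n_features, rng):
        layers: list[_nn.Layer] = [_nn.Dropout(self.dropout, rng)]
        width = n_features
        for u in self.units:
            layers.append(_nn.LSTM(width, u, rng, return_sequences=True, stateful=True))
            width = u
        layers.append(_nn.Dense(width, N_OUTPUTS, rng))
        return _nn.Sequential(layers)

    def _shuffle_batches(self):
        # one ordered pass per epoch so the carried states stay meaningful
        return False

    def _forward_eval(self, Xv, batch: int = 16):
        outs = [self.net_.forward(Xv[i:i + batch], training=False)
                for i in range(0, Xv.shape[0], batch)]
        return np.concatenate(outs, axis=0)


class RNNSeqRegressor(BaseEmgRegressor):
    """LSTM model trained on 21-frame warm-up sub-sequences (online use)."""

    kind = "RNNseq"

    def __init__(self, units=(256, 128, 64), warmup_len=20, dropout=0.1,
                 learning_rate=1e-3, batch_size=None, max_epochs=100, patience=5,
                 random_state=None, warm_start=False):
        super().__init__(dropout, learning_rate, batch_size, max_epochs,
                         patience, random_state, warm_start)
        self.units = units
        self.warmup_len = warmup_len

    def _default_batch_size(self):
        return 128

    def _views(self, X, y):
        return _views_from_arrays(X, y, "RNNseq", warmup=self.warmup_len)

    def _build_net(self, n_features, rng):
        layers: list[_nn.Layer] = [_nn.Dropout(self.dropout, rng)]
        width = n_features
        for k, u in enumerate(self.units):
            last = k == len(self.units) - 1
            layers.append(_nn.LSTM(width, u, rng,
                                   return_sequences=not last, stateful=False))
            width = u
        layers.append(_nn.Dense(width, N_OUTPUTS, rng))
        return _nn.Sequential(layers)

    def predict(self, X):
        """For every frame t, rebuild the state on frames t-20..t-1, emit t."""
        if not hasattr(self, "net_"):
            raise NotFittedError(f"{type(self).__name__} is not fitted")
        X = self._validate_X(X, fitted=True)
        n_seq, T, _ = X.shape
        out = np.empty((n_seq, T, N_OUTPUTS))
        for i, seq in enumerate(X):
            xv, _ = _subsequence_views(seq, None, self.warmup_len)
            out[i] = self._forward_eval(xv)
        return out


class CNNRegressor(BaseEmgRegressor):
    """Five 1-D temporal convolutions with a frame-wise linear output."""

    kind = "CNN"

    def __init__(self, filters=(128, 128, 128, 128, 64),
                 kernel_sizes=(32, 8, 8, 4, 4), dropout=0.1, learning_rate=1e-3,
                 batch_size=None, max_epochs=100, patience=5, random_state=None,
                 warm_start=False):
        super().__init__(dropout, learning_rate, batch_size, max_epochs,
                         patience, random_state, warm_start)
        self.filters = filters
        self.kernel_sizes = kernel_sizes

    def _build_net(self, n_features, rng):
        if len(self.filters) != len(self.kernel_sizes):
            raise ValueError("filters and kernel_sizes must have equal length")
        layers: list[_nn.Layer] = [_nn.Dropout(self.dropout, rng)]
        width = n_features
        for f, k in zip(self.filters, self.kernel_sizes):
            layers += [_nn.Conv1D(width, f, k, rng), _nn.ReLU()]
            width = f
        layers.append(_nn.Dense(width, N_OUTPUTS, rng))
        return _nn.Sequential(layers)


_KIND_TO_CLASS = {
    "RNN": RNNRegressor,
    "RNNseq": RNNSeqRegressor,
    "FNN": FNNRegressor,
    "FNNseq": FNNSeqRegressor,
    "CNN": CNNRegressor,
}


def build(spec: ArchitectureSpec, train: TrainConfig | None = None) -> BaseEmgRegressor:
    """Instantiate the estimator described by an :class:`ArchitectureSpec`.

    The returned estimator is unfitted; its network is created on ``fit``.
    """
    train = train or TrainConfig()
    common = dict(dropout=spec.dropout, learning_rate=train.learning_rate,
                  batch_size=train.batch_size, max_epochs=train.max_epochs,
                  patience=train.patience, random_state=train.seed)
    if spec.kind == "RNN":
        return RNNRegressor(units=spec.units, **common)
    if spec.kind == "RNNseq":
        return RNNSeqRegressor(units=spec.units, warmup_len=spec.warmup_len, **common)
    if spec.kind == "FNN":
        return FNNRegressor(hidden=spec.hidden, **common)
    if spec.kind == "FNNseq":
        return FNNSeqRegressor(hidden=spec.hidden, lags=spec.lags, **common)
    return CNNRegressor(filters=spec.filters, kernel_sizes=spec.kernel_sizes, **common)


def transfer_weights(source: BaseEmgRegressor, fine_tune_lr: float = 1e-4,
                     **overrides) -> BaseEmgRegressor:
    """Clone a trained predictor for fine-tuning from its current weights.

    All weights are copied; the clone keeps the source architecture, uses the
    fine-tuning learning rate and resumes training from the copied weights
    (``warm_start``).
    """
    if not hasattr(source, "net_"):
        raise NotFittedError("source predictor has no weights to transfer")
    target = clone(source)
    params = dict(learning_rate=fine_tune_lr, warm_start=True)
    params.update(overrides)
    target.set_params(**params)
    target.net_ = copy.deepcopy(source.net_)
    target.net_.reset_states()
    target.n_features_in_ = source.n_features_in_
    return target


def save_predictor(est: BaseEmgRegressor, path: str | Path) -> None:
    """Serialize a fitted predictor (architecture + weights) to ``<path>.npz``
    and ``<path>.json``."""
    if not hasattr(est, "net_"):
        raise NotFittedError("cannot serialize an unfitted predictor")
    path = Path(path)
    meta = {
        "kind": est.kind,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in est.get_params().items()},
        "n_features_in": int(est.n_features_in_),
        "feature_config": getattr(est, "feature_config_", None),
        "scalers": getattr(est, "scalers_", None),
        "history": getattr(est, "history_", None),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    np.savez(path.with_suffix(".npz"),
             **{f"w{i}": w for i, w in enumerate(est.net_.get_weights())})


def load_predictor(path: str | Path) -> BaseEmgRegressor:
    """Inverse of :func:`save_predictor`; round-trips predictions exactly."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cls = _KIND_TO_CLASS[meta["kind"]]
    params = {k: (tuple(v) if isinstance(v, list) else v)
              for k, v in meta["params"].items()}
    est = cls(**params)
    rng = np.random.default_rng(0)  # placeholder init, overwritten below
    est.net_ = est._build_net(meta["n_features_in"], rng)
    est.n_features_in_ = meta["n_features_in"]
    with np.load(path.with_suffix(".npz")) as data:
        est.net_.set_weights([data[f"w{i}"] for i in range(len(data.files))])
    if meta.get("feature_config"):
        est.feature_config_ = meta["feature_config"]
    if meta.get("scalers"):
        est.scalers_ = meta["scalers"]
    if meta.get("history"):
        est.history_ = meta["history"]
    return est
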