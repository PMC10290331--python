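"""Minimal feedforward/recurrent/convolutional network engine on numpy.

Implements exactly the layer types the EMG-envelope predictors need
(dense, ReLU, inverted dropout, stateful LSTM, 1-D "same" convolution),
hand-written backpropagation, the Adam optimizer and an early-stopping
training loop.  Everything is float64 and driven by an explicit
``numpy.random.Generator`` so that a fixed seed reproduces training
bit-for-bit on the same BLAS build.

Conventions
-----------
* 2-D tensors are (batch, features); 3-D tensors are (batch, time, features).
* ``Layer.forward`` caches whatever ``backward`` needs; a forward call
  invalidates the previous cache.
* Gradients accumulate into ``Layer.grads`` in the order of ``Layer.params``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "ReLU",
    "Dropout",
    "LSTM",
    "Conv1D",
    "Sequential",
    "Adam",
    "mse_loss",
    "fit_loop",
]


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: stateless unless documented otherwise."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def reset_states(self) -> None:
        """No-op for stateless layers."""

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


class Dense(Layer):
    """Affine map on the last axis; time-distributed when fed 3-D input."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        x2 = self._x.reshape(-1, self.n_in)
        dy2 = dy.reshape(-1, self.n_out)
        self.grads[0] += x2.T @ dy2
        self.grads[1] += dy2.sum(axis=0)
        return dy @ self.W.T


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class Dropout(Layer):
    """Inverted dropout: active only while training, identity otherwise."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTM(Layer):
    """Standard LSTM (gate order i, f, g, o) with optional statefulness.

    When ``stateful`` the final (h, c) of a forward pass seeds the next
    forward pass lane-by-lane, detached from the graph (truncated BPTT at
    sequence boundaries).  ``reset_states`` clears the carry.
    """

    def __init__(self, n_in: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = True, stateful: bool = False):
        super().__init__()
        self.n_in, self.units = n_in, units
        self.return_sequences = return_sequences
        self.stateful = stateful
        H = units
        self.W = _glorot(rng, (n_in, 4 * H), n_in, H)
        self.U = _glorot(rng, (H, 4 * H), H, H)
        self.b = np.zeros(4 * H)
        self.b[H:2 * H] = 1.0  # forget-gate bias
        self.params = [self.W, self.U, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]
        self._h0 = None
        self._c0 = None

    def reset_states(self):
        self._h0 = None
        self._c0 = None

    @property
    def states(self):
        return self._h0, self._c0

    def set_states(self, h, c):
        self._h0 = None if h is None else h.copy()
        self._c0 = None if c is None else c.copy()

    def forward(self, x, training=False):
        B, T, _ = x.shape
        H = self.units
        if self.stateful and self._h0 is not None and self._h0.shape[0] == B:
            h = self._h0.copy()
            c = self._c0.copy()
        else:
            h = np.zeros((B, H))
            c = np.zeros((B, H))
        xs_W = x @ self.W  # (B, T, 4H) precomputed input contribution
        cache = []
        hs = np.empty((B, T, H))
        for t in range(T):
            z = xs_W[:, t] + h @ self.U + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_prev = c
            c = f * c + i * g
            tc = np.tanh(c)
            h_new = o * tc
            cache.append((h, c_prev, i, f, g, o, tc))
            h = h_new
            hs[:, t] = h
        self._x = x
        self._cache = cache
        if self.stateful:
            self._h0 = h.copy()
            self._c0 = c.copy()
        return hs if self.return_sequences else hs[:, -1]

    def backward(self, dy):
        x = self._x
        B, T, _ = x.shape
        H = self.units
        dW, dU, db = self.grads
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        if self.return_sequences:
            dys = dy
        else:
            dys = np.zeros((B, T, H))
            dys[:, -1] = dy
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = dys[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)
            dW += x[:, t].T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.W.T
            dh_next = dz @ self.U.T
            dc_next = dc * f
        return dx


class Conv1D(Layer):
    """1-D convolution along time with 'same' zero padding."""

    def __init__(self, n_in: int, filters: int, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        self.n_in, self.filters, self.kernel_size = n_in, filters, kernel_size
        fan_in = kernel_size * n_in
        self.K = _glorot(rng, (kernel_size, n_in, filters), fan_in, filters)
        self.b = np.zeros(filters)
        self.params = [self.K, self.b]
        self.grads = [np.zeros_like(self.K), np.zeros_like(self.b)]
        self._pad = ((kernel_size - 1) // 2, kernel_size // 2)

    def forward(self, x, training=False):
        lo, hi = self._pad
        xp = np.pad(x, ((0, 0), (lo, hi), (0, 0)))
        # (B, T, n_in, kernel) windows over the padded time axis
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel_size, axis=1)
        self._win = win
        self._T = x.shape[1]
        y = np.tensordot(win, self.K, axes=([3, 2], [0, 1])) + self.b
        return y

    def backward(self, dy):
        lo, hi = self._pad
        B, T, _ = dy.shape[0], self._T, None
        dK = np.tensordot(self._win, dy, axes=([0, 1], [0, 1]))  # (n_in, kernel, filters)
        self.grads[0] += dK.transpose(1, 0, 2)
        self.grads[1] += dy.sum(axis=(0, 1))
        dxp = np.zeros((dy.shape[0], T + lo + hi, self.n_in))
        for k in range(self.kernel_size):
            dxp[:, k:k + T] += dy @ self.K[k].T
        return dxp[:, lo:lo + T]


class Sequential:
    """A plain layer stack with flattened parameter/gradient views."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def reset_states(self):
        for layer in self.layers:
            layer.reset_states()

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w

    def save_states(self):
        return [(l._h0.copy() if getattr(l, "_h0", None) is not None else None,
                 l._c0.copy() if getattr(l, "_c0", None) is not None else None)
                if isinstance(l, LSTM) else None for l in self.layers]

    def restore_states(self, snapshot):
        for layer, st in zip(self.layers, snapshot):
            if isinstance(layer, LSTM) and st is not None:
                layer.set_states(*st)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1.0 - b1) * g
            v[...] = b2 * v + (1.0 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over every element, and its gradient w.r.t. pred."""
    diff = pred - target
    n = diff.size
    return float(np.mean(diff * diff)), (2.0 / n) * diff


def fit_loop(net: Sequential, optimizer: Adam, batch_iter, val_fn,
             max_epochs: int, patience: int, reset_each_epoch: bool = True):
    """Generic epoch loop with early stopping on validation loss.

    ``batch_iter(epoch)`` yields (x, y) training batches; ``val_fn()``
    returns the current validation loss or ``None`` when no validation
    set exists.  Best-epoch weights are restored on exit.  Returns a
    history dict with per-epoch train/val loss.
    """
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = net.get_weights()
    best_epoch = 0
    for epoch in range(1, max_epochs + 1):
        if reset_each_epoch:
            net.reset_states()
        total, count = 0.0, 0
        for xb, yb in batch_iter(epoch):
            pred = net.forward(xb, training=True)
            loss, dloss = mse_loss(pred, yb)
            net.zero_grad()
            net.backward(dloss)
            optimizer.step(net.grads)
            total += loss * yb.size
            count += yb.size
        train_loss = total / max(count, 1)
        history["train_loss"].append(train_loss)
        if val_fn is None:
            history["val_loss"].append(np.nan)
            continue
        snapshot = net.save_states()
        net.reset_states()
        val_loss = val_fn()
        net.restore_states(snapshot)
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = net.get_weights()
            best_epoch = epoch
        elif epoch - best_epoch >= patience:
            break
    if val_fn is not None:
        net.set_weights(best_weights)
    history["best_epoch"] = best_epoch if val_fn is not None else len(history["train_loss"])
    return history
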