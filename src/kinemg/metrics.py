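"""Goodness-of-fit statistics for predicted EMG envelopes.

Conventions follow the evaluation of envelope regression: ``y`` is the
recorded (original) signal, ``x`` the generated one.  Five statistics are
reported per channel and channel-averaged:

* ``mse``     — mean squared error, also the training loss.
* ``pearson_r`` (and r²) — Pearson correlation; invariant under positive
  affine rescaling of either signal, so it rates timing/shape but not
  amplitude.
* ``r_squared_determination`` — R² = 1 − Σ(y−x)² / Σ(y−ȳ)²; compares the
  residual against a mean-signal baseline; ≤ 1, unbounded below.
* ``zero_line_score`` — Z_s = 100·(1 − Σ(y−x)² / Σy²); compares the residual
  against the *zero line* instead of the mean, which suits EMG envelopes
  whose channels rest near zero most of the time.  100 = perfect match,
  0 = no better than predicting constant zero, unbounded below.

``vaf`` and ``nrmse`` are provided for comparison with other reporting
conventions; they are not part of :func:`report`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "mse",
    "pearson_r",
    "r_squared_determination",
    "zero_line_score",
    "vaf",
    "nrmse",
    "MetricReport",
    "report",
]

METRIC_NAMES = ("MSE", "r", "r2", "R2", "Zs")


def _check(y, x) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if y.shape != x.shape:
        raise ValueError(f"shape mismatch: original {y.shape} vs predicted {x.shape}")
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
        raise ValueError("inputs must be finite")
    return y, x


def mse(y, x) -> float:
    """Mean squared error (1/n) Σ (y_i − x_i)²."""
    y, x = _check(y, x)
    return float(np.mean((y - x) ** 2))


def pearson_r(y, x) -> float:
    """Pearson correlation coefficient between original and prediction.

    Raises on constant input, where the coefficient is undefined.
    """
    y, x = _check(y, x)
    yc = y - y.mean()
    xc = x - x.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        raise ValueError("correlation undefined for a constant signal")
    return float((xc @ yc) / denom)


def r_squared_determination(y, x) -> float:
    """Coefficient of determination R² = 1 − Σ(y−x)² / Σ(y−ȳ)²."""
    y, x = _check(y, x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R² undefined for a constant original signal")
    return 1.0 - float(np.sum((y - x) ** 2)) / ss_tot


def zero_line_score(y, x) -> float:
    """Zero-line score Z_s = 100 · (1 − Σ(y−x)² / Σ(y−0)²)."""
    y, x = _check(y, x)
    ss_zero = float(np.sum(y * y))
    if ss_zero == 0.0:
        raise ValueError("zero-line score undefined for an identically zero original signal")
    return 100.0 * (1.0 - float(np.sum((y - x) ** 2)) / ss_zero)


def vaf(y, x) -> float:
    """Variance accounted for: 1 − Var(y − x) / Var(y) (comparison aid)."""
    y, x = _check(y, x)
    var_y = float(np.var(y))
    if var_y == 0.0:
        raise ValueError("VAF undefined for a constant original signal")
    return 1.0 - float(np.var(y - x)) / var_y


def nrmse(y, x) -> float:
    """RMSE normalized by the original signal's range (comparison aid)."""
    y, x = _check(y, x)
    rng = float(y.max() - y.min())
    if rng == 0.0:
        raise ValueError("NRMSE undefined for a constant original signal")
    return float(np.sqrt(np.mean((y - x) ** 2))) / rng


@dataclass
class MetricReport:
    """Per-channel and channel-averaged statistics for a prediction set."""

    per_channel: dict[str, np.ndarray]      # metric name -> (n_channels,)
    average: dict[str, float]               # metric name -> mean over channels
    n_sequences: int
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Channels as columns 1..8 plus 'Average', metrics as rows."""
        n_ch = len(next(iter(self.per_channel.values())))
        frame = pd.DataFrame(self.per_channel,
                             index=[str(i + 1) for i in range(n_ch)]).T
        frame["Average"] = [self.average[m] for m in frame.index]
        return frame


def report(pairs, metadata: dict | None = None, per_sequence: bool = False) -> MetricReport:
    """Evaluate a set of (original, predicted) sequence pairs.

    Each element of ``pairs`` is a tuple of (frames x channels) arrays.  By
    default sequences are concatenated per channel before the statistics are
    computed (matching channel-wise reporting over a whole test set);
    ``per_sequence`` instead averages per-sequence statistics.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty prediction set")
    fns = {"MSE": mse, "r": pearson_r, "r2": lambda y, x: pearson_r(y, x) ** 2,
           "R2": r_squared_determination, "Zs": zero_line_score}
    n_ch = pairs[0][0].shape[1]
    if per_sequence:
        per_channel = {
            m: np.array([np.mean([fn(y[:, c], x[:, c]) for y, x in pairs])
                         for c in range(n_ch)])
            for m, fn in fns.items()
        }
    else:
        y_all = np.vstack([y for y, _ in pairs])
        x_all = np.vstack([x for _, x in pairs])
        per_channel = {m: np.array([fn(y_all[:, c], x_all[:, c]) for c in range(n_ch)])
                       for m, fn in fns.items()}
    average = {m: float(v.mean()) for m, v in per_channel.items()}
    return MetricReport(per_channel=per_channel, average=average,
                        n_sequences=len(pairs), metadata=metadata or {})
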