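"""Raw recording -> model-ready sequence pairs.

Fixed pipeline order:

* EMG: baseline correction -> 6-SD outlier repair -> 200-ms windowed RMS
  (simultaneously downsampling to the 60-Hz motion timestamps) ->
  per-subject min-max normalization to [0, 1] -> cue-anchored cuts of
  457 frames.
* Motion: third-order Savitzky-Golay smoothing of the joint angles ->
  forward-difference velocity/acceleration -> feature assembly (ANG / VEL /
  ACC / ALL / EEF / EEFplus) -> per-subject min-max normalization to
  [-1, 1] -> the same 457-frame cuts.

Derivatives are computed in physical units before normalization and then
normalized as channels of their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LSQUnivariateSpline
from scipy.signal import savgol_filter

from .synth import RawRecording

__all__ = [
    "SEQUENCE_LENGTH",
    "FEATURE_WIDTHS",
    "ChannelScaler",
    "SequencePair",
    "baseline_correct",
    "repair_outliers",
    "moving_rms",
    "savgol_positions",
    "differentiate",
    "normalize",
    "build_features",
    "segment_sequences",
    "preprocess_recording",
]

SEQUENCE_LENGTH = 457

FEATURE_WIDTHS = {"ANG": 6, "VEL": 6, "ACC": 6, "ALL": 18, "EEF": 7, "EEFplus": 21}


def baseline_correct(emg_raw: np.ndarray, rate: float, rest_duration: float = 4.0) -> np.ndarray:
    """Subtract each channel's mean over the leading rest period."""
    emg_raw = np.asarray(emg_raw)
    if not np.all(np.isfinite(emg_raw)):
        raise ValueError("EMG contains non-finite samples")
    n_rest = int(round(rest_duration * rate))
    if n_rest < 1 or n_rest > emg_raw.shape[0]:
        raise ValueError("recording has no leading rest window to estimate the baseline from")
    return emg_raw - emg_raw[:n_rest].mean(axis=0, keepdims=True)


def repair_outliers(emg_raw: np.ndarray, rate: float, k_sd: float = 6.0,
                    margin: float = 0.05, max_flagged: float = 0.2,
                    knot_spacing: float = 0.025,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Flag samples beyond ``k_sd`` standard deviations and repair them.

    Each flagged excursion (extended by a ``margin``-second margin on both
    sides) gets a cubic least-squares trend spline (interior knots every
    ``knot_spacing`` seconds) fitted and subtracted, removing the slow
    cable-movement component.  Samples that afterwards remain beyond the
    k-SD band *and* beyond k local standard deviations — local scale taken
    from the unflagged samples of the same window, so genuine
    amplitude-modulated bursts are left alone — are bridged by linear
    interpolation between their nearest in-band neighbours.  Samples
    outside the margins are untouched.

    Returns (repaired signal, boolean mask of originally flagged samples).
    """
    emg = np.array(emg_raw, dtype=float, copy=True)
    n, n_ch = emg.shape
    mask = np.zeros_like(emg, dtype=bool)
    pad = max(int(round(margin * rate)), 1)
    step = max(int(round(knot_spacing * rate)), 4)
    for c in range(n_ch):
        x = emg[:, c]
        mu, sd = x.mean(), x.std()
        if sd == 0:
            raise ValueError(f"channel {c} has zero variance")
        flagged = np.abs(x - mu) > k_sd * sd
        if not flagged.any():
            continue
        if flagged.mean() > max_flagged:
            raise ValueError(
                f"channel {c}: {flagged.mean():.0%} of samples flagged as outliers; "
                "input looks corrupt")
        mask[:, c] = flagged
        idx = np.flatnonzero(flagged)
        # group flagged samples into runs, each extended by the margin
        splits = np.flatnonzero(np.diff(idx) > 2 * pad) + 1
        for run in np.split(idx, splits):
            lo = max(run[0] - pad, 0)
            hi = min(run[-1] + pad + 1, n)
            t = np.arange(lo, hi)
            w = x[lo:hi]
            if len(t) > 2 * step + 8:
                knots = t[step:-step:step]
                spline = LSQUnivariateSpline(t, w, knots, k=3)
                x[lo:hi] = w - (spline(t) - mu)
            window_flags = flagged[lo:hi]
            local_sd = x[lo:hi][~window_flags].std() if (~window_flags).any() else sd
            bound = k_sd * max(sd, local_sd)
            still = np.abs(x[lo:hi] - mu) > bound
            if still.any():
                good = np.flatnonzero(~still)
                bad = np.flatnonzero(still)
                if len(good) >= 2:
                    x[lo + bad] = np.interp(bad, good, x[lo + good])
                else:
                    x[lo + bad] = mu
        emg[:, c] = x
    return emg, mask


def moving_rms(emg_raw: np.ndarray, emg_rate: float, target_times: np.ndarray,
               window: float = 0.2) -> np.ndarray:
    """Windowed RMS of the raw signal around each target timestamp.

    For each target time t the RMS of all raw samples with
    ``|sample_time - t| <= window / 2`` is returned, smoothing and
    downsampling in one step.  Boundary windows are truncated, never padded.
    """
    emg_raw = np.asarray(emg_raw, dtype=float)
    target_times = np.asarray(target_times, dtype=float)
    n = emg_raw.shape[0]
    sample_times = np.arange(n) / emg_rate
    half = window / 2.0
    lo = np.searchsorted(sample_times, target_times - half, side="left")
    hi = np.searchsorted(sample_times, target_times + half, side="right")
    if np.any(hi <= lo):
        raise ValueError("empty RMS window: raw EMG does not cover all target timestamps")
    csum = np.concatenate([np.zeros((1, emg_raw.shape[1])),
                           np.cumsum(emg_raw ** 2, axis=0)])
    counts = (hi - lo).astype(float)[:, None]
    return np.sqrt((csum[hi] - csum[lo]) / counts)


def savgol_positions(angles: np.ndarray, order: int = 3, window_frames: int = 31) -> np.ndarray:
    """Savitzky-Golay smoothing of joint angles (local cubic least squares)."""
    angles = np.asarray(angles, dtype=float)
    if window_frames % 2 == 0 or window_frames <= order:
        raise ValueError("window_frames must be odd and larger than the polynomial order")
    if angles.shape[0] < window_frames:
        raise ValueError("sequence shorter than the filter window")
    return savgol_filter(angles, window_frames, order, axis=0, mode="interp")


def differentiate(series: np.ndarray, rate: float = 60.0) -> np.ndarray:
    """Forward difference f(n+1) - f(n), scaled to units per second.

    The final frame replicates the penultimate derivative so the output
    keeps the input length; applying the operator twice yields acceleration.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 2:
        raise ValueError("need at least 2 frames to differentiate")
    out = np.empty_like(series)
    out[:-1] = np.diff(series, axis=0) * rate
    out[-1] = out[-2]
    return out


class ChannelScaler:
    """Per-channel min-max scaler with exact inverse and clipped transforms.

    EMG maps to [0, 1] and motion to [-1, 1].  Applying stored parameters to
    new data of the same subject may exceed the fit range; such values are
    clipped and the clipped fraction recorded in ``clip_fraction_``.
    """

    def __init__(self, mode: str):
        if mode not in ("emg", "motion"):
            raise ValueError("mode must be 'emg' or 'motion'")
        self.mode = mode
        self.feature_range = (0.0, 1.0) if mode == "emg" else (-1.0, 1.0)

    def fit(self, X: np.ndarray) -> "ChannelScaler":
        X = np.asarray(X, dtype=float)
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        if np.any(self.data_max_ == self.data_min_):
            bad = np.flatnonzero(self.data_max_ == self.data_min_)
            raise ValueError(f"constant channel(s) {bad.tolist()} cannot be min-max scaled")
        self.clip_fraction_ = 0.0
        return self

    def transform(self, X: np.ndarray, clip: bool = True) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        a, b = self.feature_range
        scaled = a + (X - self.data_min_) / (self.data_max_ - self.data_min_) * (b - a)
        if clip:
            out_of_range = (scaled < a) | (scaled > b)
            self.clip_fraction_ = float(out_of_range.mean())
            scaled = np.clip(scaled, a, b)
        return scaled

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        a, b = self.feature_range
        return self.data_min_ + (np.asarray(X, float) - a) / (b - a) * (self.data_max_ - self.data_min_)

    def to_dict(self) -> dict:
        return {"mode": self.mode, "data_min": self.data_min_.tolist(),
                "data_max": self.data_max_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelScaler":
        sc = cls(d["mode"])
        sc.data_min_ = np.asarray(d["data_min"], float)
        sc.data_max_ = np.asarray(d["data_max"], float)
        sc.clip_fraction_ = 0.0
        return sc


def normalize(series: np.ndarray, mode: str,
              fit_data: np.ndarray | None = None) -> tuple[np.ndarray, ChannelScaler]:
    """Min-max normalize ``series``; parameters fitted on ``fit_data``.

    ``fit_data`` defaults to the series itself and must come from a single
    subject — normalization is always per subject.
    """
    scaler = ChannelScaler(mode).fit(series if fit_data is None else fit_data)
    return scaler.transform(series), scaler


def _quat_continuous(quat: np.ndarray) -> np.ndarray:
    """Resolve the q/-q ambiguity by hemisphere continuity along time."""
    q = np.array(quat, dtype=float, copy=True)
    flips = np.cumsum(np.einsum("ij,ij->i", q[1:], q[:-1]) < 0) % 2
    q[1:][flips == 1] *= -1.0
    return q


def build_features(motion: np.ndarray, feature_config: str, rate: float = 60.0,
                   smoothed: bool = True, savgol_window: int = 31) -> np.ndarray:
    """Assemble the model input matrix from a (frames x 13) motion block.

    Columns of ``motion``: 6 joint angles (deg), hand x/y/z (m), quaternion
    w/x/y/z.  Configurations: ANG / VEL / ACC (6 each), ALL (18 = angles +
    velocity + acceleration), EEF (7 = position + quaternion), EEFplus (21 =
    EEF + its first and second forward differences).
    """
    if feature_config not in FEATURE_WIDTHS:
        raise ValueError(f"unknown feature config {feature_config!r}; "
                         f"choose from {sorted(FEATURE_WIDTHS)}")
    motion = np.asarray(motion, dtype=float)
    if motion.shape[1] != 13:
        raise ValueError("motion block must have 13 columns (6 angles + hand pose)")
    angles = motion[:, :6]
    if not smoothed:
        angles = savgol_positions(angles, window_frames=savgol_window)
    if feature_config in ("ANG", "VEL", "ACC", "ALL"):
        vel = differentiate(angles, rate)
        acc = differentiate(vel, rate)
        return {"ANG": angles, "VEL": vel, "ACC": acc,
                "ALL": np.hstack([angles, vel, acc])}[feature_config]
    eef = np.hstack([motion[:, 6:9], _quat_continuous(motion[:, 9:13])])
    if feature_config == "EEF":
        return eef
    d1 = differentiate(eef, rate)
    d2 = differentiate(d1, rate)
    return np.hstack([eef, d1, d2])


@dataclass
class SequencePair:
    """One segmented trial: motion features and EMG envelope, 457 frames."""

    motion: np.ndarray   # (457, n_features)
    emg: np.ndarray      # (457, 8)
    subject: int
    task: int
    repetition: int
    feature_config: str = "ALL"

    def __post_init__(self):
        if self.motion.shape[0] != self.emg.shape[0]:
            raise ValueError("motion and EMG members must share the frame count")

    @property
    def key(self) -> tuple[int, int, int]:
        return (self.subject, self.task, self.repetition)


def _cut(frames: np.ndarray, cue: int, seq_len: int, rest_frame: np.ndarray | None) -> np.ndarray:
    window = frames[cue:cue + seq_len]
    missing = seq_len - window.shape[0]
    if missing > 0:
        if rest_frame is None:
            raise ValueError("cue too close to the recording end and no rest frames available")
        window = np.vstack([window, np.tile(rest_frame, (missing, 1))])
    return window


def segment_sequences(motion_features: np.ndarray, envelope: np.ndarray,
                      cue_onsets: np.ndarray, labels: list[tuple[int, int]],
                      subject: int, seq_len: int = SEQUENCE_LENGTH,
                      feature_config: str = "ALL",
                      rest_frames: tuple[np.ndarray, np.ndarray] | None = None,
                      ) -> list[SequencePair]:
    """Cut cue-anchored windows of ``seq_len`` frames into SequencePairs.

    Windows reaching past the end of the recording are right-padded with the
    supplied rest-state frames (defaults to the recording's first frame,
    which lies in the initial rest period).
    """
    if len(cue_onsets) != len(labels):
        raise ValueError("cue_onsets and labels must have the same length")
    if rest_frames is None:
        rest_m, rest_e = motion_features[0], envelope[0]
    else:
        rest_m, rest_e = rest_frames
    pairs = []
    for cue, (task, rep) in zip(np.asarray(cue_onsets, int), labels):
        pairs.append(SequencePair(
            motion=_cut(motion_features, cue, seq_len, rest_m),
            emg=_cut(envelope, cue, seq_len, rest_e),
            subject=subject, task=int(task), repetition=int(rep),
            feature_config=feature_config,
        ))
    return pairs


def preprocess_recording(recording: RawRecording, feature_config: str = "ALL",
                         rest_duration: float | None = None,
                         savgol_window: int = 31,
                         normalize_channels: bool = True,
                         ) -> list[SequencePair]:
    """Run the full fixed-order pipeline on one raw recording.

    With ``normalize_channels`` the min-max parameters are fitted on the full
    session; protocol runners instead call the stages themselves and fit
    normalization on the training portion only.
    """
    rest = 4.0 if rest_duration is None else rest_duration
    emg = baseline_correct(recording.emg, recording.emg_rate, rest)
    emg, _ = repair_outliers(emg, recording.emg_rate)
    t60 = np.arange(recording.motion.shape[0]) / recording.motion_rate
    envelope = moving_rms(emg, recording.emg_rate, t60)
    motion = recording.motion.copy()
    motion[:, :6] = savgol_positions(motion[:, :6], window_frames=savgol_window)
    features = build_features(motion, feature_config, rate=recording.motion_rate)
    if normalize_channels:
        envelope, _ = normalize(envelope, "emg")
        features, _ = normalize(features, "motion")
    return segment_sequences(features, envelope, recording.cue_onsets,
                             recording.labels, recording.subject_id,
                             feature_config=feature_config)
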