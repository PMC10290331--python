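"""Preprocessing chain: each stage against its closed-form oracle."""

import numpy as np
import pytest

from kinemg.preprocess import (
    FEATURE_WIDTHS,
    SEQUENCE_LENGTH,
    ChannelScaler,
    baseline_correct,
    build_features,
    differentiate,
    moving_rms,
    normalize,
    preprocess_recording,
    repair_outliers,
    savgol_positions,
    segment_sequences,
)
from kinemg.protocols import pairs_from_recordings


class TestBaselineCorrect:
    def test_constant_offset_removed(self):
        x = np.full((1000, 2), 5.0)
        out = baseline_correct(x, rate=100.0, rest_duration=1.0)
        assert np.abs(out[:100].mean(axis=0)).max() < 1e-9

    def test_zero_mean_rest_unchanged(self, rng):
        x = rng.standard_normal((2000, 3))
        x -= x[:500].mean(axis=0)
        out = baseline_correct(x, rate=500.0, rest_duration=1.0)
        assert np.allclose(out, x)

    def test_offset_plus_sinusoid_preserves_sinusoid(self):
        t = np.arange(4000) / 1000.0
        sine = np.sin(2 * np.pi * 7 * t)[:, None]
        # rest window holds an offset only; sinusoid rides on top afterwards
        x = np.full((4000, 1), 5.0)
        x[1000:] += sine[1000:]
        out = baseline_correct(x, rate=1000.0, rest_duration=1.0)
        assert np.allclose(out[1000:], sine[1000:], atol=1e-9)
        assert np.allclose(out[:1000], 0.0, atol=1e-9)

    def test_missing_rest_window_errors(self):
        with pytest.raises(ValueError, match="rest"):
            baseline_correct(np.zeros((10, 2)), rate=100.0, rest_duration=1.0)


class TestRepairOutliers:
    def test_clean_gaussian_untouched(self, rng):
        x = rng.standard_normal((20000, 2))
        out, mask = repair_outliers(x, rate=2000.0)
        assert not mask.any()
        assert np.array_equal(out, x)

    def test_single_huge_spike_repaired_below_bound(self, rng):
        x = rng.standard_normal((20000, 2))
        x[5000, 0] = 100.0 * x[:, 0].std()
        out, mask = repair_outliers(x, rate=2000.0)
        assert mask[5000, 0]
        assert abs(out[5000, 0] - x[:, 0].mean()) < 6.0 * x[:, 0].std()

    def test_channel_independence(self, rng):
        x = rng.standard_normal((20000, 2))
        x[5000, 0] = 80.0
        out, _ = repair_outliers(x, rate=2000.0)
        assert np.array_equal(out[:, 1], x[:, 1])

    def test_corrupt_channel_rejected(self, rng):
        # the guard needs a permissive threshold to be reachable: with the
        # default k=6 Chebyshev caps the flagged fraction at 1/36
        x = rng.normal(0.0, 0.1, (1000, 1))
        x[:250, 0] = 5.0  # 25 % of the channel sits far off the bulk
        with pytest.raises(ValueError, match="corrupt"):
            repair_outliers(x, rate=1000.0, k_sd=1.0)


class TestMovingRms:
    def test_constant_signal(self):
        x = np.full((2222, 1), 3.0)
        t = np.arange(0.1, 0.9, 1 / 60.0)
        out = moving_rms(x, 2222.0, t)
        assert np.allclose(out, 3.0)

    def test_two_sample_window_closed_form(self):
        # RMS of samples [3, 4] = sqrt((9 + 16) / 2) = sqrt(12.5)
        x = np.array([[3.0], [4.0]])
        out = moving_rms(x, 10.0, np.array([0.05]), window=0.2)
        assert out[0, 0] == pytest.approx(np.sqrt(12.5))

    def test_white_noise_rms_estimates_sigma(self, rng):
        sigma = 0.7
        x = rng.normal(0.0, sigma, size=(22220, 1))
        t = np.arange(0.2, 9.8, 1 / 60.0)
        out = moving_rms(x, 2222.0, t)
        m = 0.2 * 2222
        assert np.abs(out - sigma).max() < 3.0 * sigma / np.sqrt(m)

    def test_empty_window_errors(self):
        with pytest.raises(ValueError, match="empty"):
            moving_rms(np.ones((10, 1)), 2222.0, np.array([99.0]))


class TestSavgol:
    def test_exact_cubic_reproduced(self):
        t = np.linspace(-2, 2, 200)
        cubic = (t ** 3 - 2 * t)[:, None]
        assert np.abs(savgol_positions(cubic) - cubic).max() < 1e-9

    def test_constant_preserved(self):
        x = np.full((100, 3), 4.2)
        assert np.allclose(savgol_positions(x), 4.2)

    def test_denoises_toward_underlying_cubic(self, rng):
        t = np.linspace(-2, 2, 400)
        cubic = (0.5 * t ** 3)[:, None]
        noisy = cubic + rng.normal(0, 0.3, size=cubic.shape)
        smoothed = savgol_positions(noisy)
        assert np.mean((smoothed - cubic) ** 2) < np.mean((noisy - cubic) ** 2)

    def test_invalid_window_errors(self):
        x = np.zeros((100, 1))
        with pytest.raises(ValueError, match="odd"):
            savgol_positions(x, window_frames=30)
        with pytest.raises(ValueError, match="shorter"):
            savgol_positions(np.zeros((5, 1)), window_frames=31)


class TestDifferentiate:
    def test_linear_ramp(self):
        f = (2.0 * np.arange(100))[:, None]
        assert np.allclose(differentiate(f, rate=60.0), 120.0)

    def test_constant_gives_zero(self):
        assert np.allclose(differentiate(np.full((50, 2), 3.0)), 0.0)

    def test_forward_difference_with_last_frame_rule(self):
        f = np.array([0.0, 1.0, 4.0, 9.0])[:, None]
        out = differentiate(f, rate=1.0)
        assert np.allclose(out.ravel(), [1.0, 3.0, 5.0, 5.0])

    def test_single_frame_errors(self):
        with pytest.raises(ValueError, match="2 frames"):
            differentiate(np.zeros((1, 2)))

    def test_discrete_fundamental_theorem(self, rng):
        """differentiate o cumulative-sum is the identity up to the
        replicated last frame."""
        d = rng.standard_normal((200, 3))
        rate = 60.0
        f = np.vstack([np.zeros(3), np.cumsum(d, axis=0)[:-1]]) / rate
        out = differentiate(f, rate=rate)
        assert np.allclose(out[:-1], d[:-1])
        assert np.allclose(out[-1], d[-2])


class TestNormalize:
    def test_emg_and_motion_ranges(self):
        emg, _ = normalize(np.linspace(2, 6, 50)[:, None], "emg")
        assert emg.min() == pytest.approx(0.0)
        assert emg.max() == pytest.approx(1.0)
        motion, _ = normalize(np.linspace(-3, 3, 50)[:, None], "motion")
        assert motion.min() == pytest.approx(-1.0)
        assert motion.max() == pytest.approx(1.0)

    def test_round_trip_inverse(self, rng):
        x = rng.uniform(-5, 9, size=(300, 4))
        scaled, scaler = normalize(x, "motion")
        assert np.abs(scaler.inverse_transform(scaled) - x).max() < 1e-9

    def test_constant_channel_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize(np.ones((10, 2)), "emg")

    def test_out_of_range_values_clipped_and_logged(self, rng):
        scaler = ChannelScaler("emg").fit(rng.uniform(0, 1, (100, 1)))
        out = scaler.transform(np.array([[5.0], [0.5], [-3.0]]))
        assert out.min() >= 0.0 and out.max() <= 1.0
        assert scaler.clip_fraction_ == pytest.approx(2 / 3)


class TestFeaturesAndSegmentation:
    @pytest.mark.parametrize("config,width", sorted(FEATURE_WIDTHS.items()))
    def test_feature_widths(self, config, width, small_recordings):
        motion = small_recordings[0].motion[:500]
        assert build_features(motion, config).shape[1] == width

    def test_vel_of_constant_pose_is_zero(self):
        motion = np.hstack([np.full((100, 6), 10.0), np.zeros((100, 3)),
                            np.tile([1.0, 0, 0, 0], (100, 1))])
        assert np.allclose(build_features(motion, "VEL"), 0.0)

    def test_unknown_config_rejected(self, small_recordings):
        with pytest.raises(ValueError, match="unknown feature config"):
            build_features(small_recordings[0].motion, "XYZ")

    def test_segment_count_equals_cue_count(self, small_recordings, small_pairs):
        assert len(small_pairs) == sum(len(r.cue_onsets) for r in small_recordings)
        assert all(p.motion.shape[0] == SEQUENCE_LENGTH for p in small_pairs)
        assert all(p.emg.shape[0] == SEQUENCE_LENGTH for p in small_pairs)

    def test_trailing_cue_right_padded_with_rest(self):
        """A cue 450 frames before the end needs exactly 7 rest frames."""
        n = 450
        feats = np.arange(n * 2, dtype=float).reshape(n, 2)
        env = np.ones((n, 8))
        rest = (np.full(2, -1.0), np.full(8, 0.5))
        pairs = segment_sequences(feats, env, [0], [(0, 0)], subject=1,
                                  rest_frames=rest)
        assert pairs[0].motion.shape[0] == SEQUENCE_LENGTH
        assert np.all(pairs[0].motion[-7:] == -1.0)
        assert np.all(pairs[0].emg[-7:] == 0.5)

    def test_trailing_cue_without_rest_frames_errors(self):
        feats = np.zeros((450, 2))
        env = np.zeros((450, 8))
        with pytest.raises(ValueError, match="rest"):
            segment_sequences(feats, env, [0], [(0, 0)], subject=1,
                              rest_frames=(None, None))


class TestPipeline:
    def test_envelope_recovery_from_am_carrier(self, small_recordings):
        """Windowed RMS recovers the ground-truth activation to < 5 %."""
        from kinemg.preprocess import baseline_correct, moving_rms, repair_outliers
        rec = small_recordings[0]
        emg = baseline_correct(rec.emg, rec.emg_rate)
        emg, _ = repair_outliers(emg, rec.emg_rate)
        t60 = np.arange(rec.motion.shape[0]) / rec.motion_rate
        env = moving_rms(emg, rec.emg_rate, t60)
        truth = rec.activation
        rel = np.sqrt(np.mean((env - truth) ** 2) / np.mean(truth ** 2))
        assert rel < 0.05

    def test_pipeline_order_is_fixed(self, small_recordings):
        """The convenience pipeline equals the documented stage order and
        differs when RMS and normalization are permuted."""
        from kinemg.preprocess import baseline_correct, moving_rms, repair_outliers
        rec = small_recordings[0]
        pairs = preprocess_recording(rec)
        emg = baseline_correct(rec.emg, rec.emg_rate)
        emg, _ = repair_outliers(emg, rec.emg_rate)
        t60 = np.arange(rec.motion.shape[0]) / rec.motion_rate
        env = moving_rms(emg, rec.emg_rate, t60)
        env_norm, _ = normalize(env, "emg")
        motion = rec.motion.copy()
        motion[:, :6] = savgol_positions(motion[:, :6])
        feats = build_features(motion, "ALL")
        feats_norm, _ = normalize(feats, "motion")
        manual = segment_sequences(feats_norm, env_norm, rec.cue_onsets,
                                   rec.labels, rec.subject_id)
        for p, q in zip(pairs, manual):
            assert np.array_equal(p.emg, q.emg)
            assert np.array_equal(p.motion, q.motion)
        # permuting normalization before RMS changes the result
        env_permuted, _ = normalize(
            moving_rms(normalize(emg, "emg")[0], rec.emg_rate, t60), "emg")
        assert not np.allclose(env_permuted, env_norm)
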