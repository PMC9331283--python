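"""Acoustic feature unit tests against independent brute-force oracles."""
from __future__ import annotations

import numpy as np
import pytest

from readtask.audio import (
    DegenerateInputError,
    afvc,
    baseline_intensity_stats,
    baseline_pitch_stats,
    delta2_mfcc,
    frame_signal,
    intensity_means,
    mfcc,
    pivd,
)
from readtask.datatypes import AudioSignal, FrameParams, IntensityTrack


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive loops, no reuse of library code)
# ---------------------------------------------------------------------------


def oracle_pivd(values):
    num_f = len(values)
    diffs = [values[i + 1] - values[i] for i in range(num_f - 1)]
    mean = sum(diffs) / len(diffs)
    return (sum((d - mean) ** 2 for d in diffs) / (num_f - 1)) ** 0.5


def oracle_delta2(matrix):
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    out = np.zeros_like(m)
    for i in range(n):
        for j in range(k):
            a = m[max(0, i - 2), j]
            b = m[max(0, i - 1), j]
            c = m[min(n - 1, i + 1), j]
            d = m[min(n - 1, i + 2), j]
            out[i, j] = (-2 * a - b + c + 2 * d) / 3.0
    return out


def oracle_afvc(m, dm):
    ps = [float(np.mean(np.asarray(m)[:, j])) for j in range(12)]
    ps += [float(np.mean(np.asarray(dm)[:, j])) for j in range(12)]
    mean = sum(ps) / 24.0
    sd = (sum((v - mean) ** 2 for v in ps) / 24.0) ** 0.5
    return sd / abs(mean)


# ---------------------------------------------------------------------------
# framing and intensity
# ---------------------------------------------------------------------------


class TestFraming:
    def test_exact_single_frame(self):
        sig = AudioSignal(np.ones(400), rate=8000)
        frames = frame_signal(sig, FrameParams(400, 200))
        assert frames.shape == (1, 400)

    def test_hop_enumeration(self):
        sig = AudioSignal(np.arange(1000.0) / 1000, rate=8000)
        frames = frame_signal(sig, FrameParams(400, 200))
        assert frames.shape == (4, 400)
        starts = [int(round(f[0] * 1000)) for f in frames]
        assert starts == [0, 200, 400, 600]

    def test_too_short_signal_rejected(self):
        sig = AudioSignal(np.ones(399), rate=8000)
        with pytest.raises(ValueError):
            frame_signal(sig, FrameParams(400, 200))

    def test_intensity_conventions(self):
        frames = np.array([[0.5, 0.5, 0.5, 0.5], [0.0, 0.0, 0.0, 0.0]])
        assert intensity_means(frames, "power").values[0] == pytest.approx(0.25)
        assert intensity_means(frames, "amplitude").values[0] == pytest.approx(0.5)
        assert intensity_means(frames, "power").values[1] == 0.0

    def test_intensity_mean_of_squares(self):
        frames = np.array([[0.1, -0.3, 0.2, 0.0]])
        assert intensity_means(frames).values[0] == pytest.approx(0.035)


class TestPIVD:
    def test_flat_track_is_zero(self):
        assert pivd(IntensityTrack(np.full(50, 3.7))) == 0.0

    def test_linear_ramp_is_zero(self):
        assert pivd(IntensityTrack(np.arange(30.0))) == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        track = IntensityTrack(np.array([1.0, 3.0, 2.0, 5.0]))
        assert pivd(track) == pytest.approx(oracle_pivd([1.0, 3.0, 2.0, 5.0]), rel=1e-12)

    def test_matches_oracle_on_random_tracks(self, rng):
        for _ in range(100):
            values = rng.normal(5.0, 2.0, size=rng.integers(3, 40))
            assert pivd(IntensityTrack(values)) == pytest.approx(
                oracle_pivd(list(values)), rel=1e-10
            )

    def test_shift_invariance_and_scaling(self, rng):
        for _ in range(25):
            values = rng.gamma(2.0, 1.0, size=20)
            base = pivd(IntensityTrack(values))
            assert pivd(IntensityTrack(values + 11.3)) == pytest.approx(base, abs=1e-12)
            assert pivd(IntensityTrack(3.5 * values)) == pytest.approx(3.5 * base, rel=1e-10)

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            pivd(IntensityTrack(np.array([1.0, 2.0])))


class TestMFCC:
    def test_twelve_columns(self, sine_signal):
        assert mfcc(sine_signal).shape[1] == 12

    def test_silence_rows_identical(self):
        sig = AudioSignal(np.zeros(22050), rate=22050)
        m = mfcc(sig)
        assert np.ptp(m, axis=0).max() == 0.0

    def test_deterministic(self, sine_signal):
        assert np.array_equal(mfcc(sine_signal), mfcc(sine_signal))

    def test_too_short_rejected(self):
        sig = AudioSignal(np.ones(600), rate=22050)
        with pytest.raises(ValueError):
            mfcc(sig)


class TestDelta2:
    def test_constant_matrix_gives_zero(self):
        m = np.full((10, 12), 2.5)
        assert np.allclose(delta2_mfcc(m), 0.0)

    def test_interior_hand_value(self):
        col = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = delta2_mfcc(col[:, None])
        assert out[2, 0] == pytest.approx(10.0 / 3.0)

    def test_matches_oracle_on_random_matrices(self, rng):
        for _ in range(100):
            m = rng.normal(size=(rng.integers(5, 20), rng.integers(1, 12)))
            assert np.allclose(delta2_mfcc(m), oracle_delta2(m), rtol=1e-10, atol=1e-12)

    def test_alternating_column(self):
        col = np.array([1.0, -1.0] * 5)
        out = delta2_mfcc(col[:, None])
        kernel = np.array([-2.0, -1.0, 0.0, 1.0, 2.0]) / 3.0
        expected = float(np.dot(kernel, col[2:7]))
        assert out[4, 0] == pytest.approx(expected)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            delta2_mfcc(np.ones((4, 12)))


class TestAFVC:
    def test_equal_means_give_zero(self):
        m = np.full((6, 12), 3.0)
        dm = np.full((6, 12), 3.0)
        assert afvc(m, dm) == 0.0

    def test_scale_invariance(self, rng):
        m = rng.normal(2.0, 1.0, size=(8, 12))
        dm = rng.normal(2.0, 1.0, size=(8, 12))
        assert afvc(4.0 * m, 4.0 * dm) == pytest.approx(afvc(m, dm), rel=1e-10)

    def test_ones_and_threes(self):
        m = np.ones((5, 12))
        dm = np.full((5, 12), 3.0)
        assert afvc(m, dm) == pytest.approx(0.5)

    def test_matches_oracle_on_random_matrices(self, rng):
        for _ in range(100):
            m = rng.normal(1.5, 1.0, size=(rng.integers(1, 15), 12))
            dm = rng.normal(1.5, 1.0, size=m.shape)
            if abs(np.concatenate([m.mean(0), dm.mean(0)]).mean()) < 1e-6:
                continue
            assert afvc(m, dm) == pytest.approx(oracle_afvc(m, dm), rel=1e-10)

    def test_near_zero_mean_is_degenerate(self):
        m = np.ones((4, 12)) * 1e-12
        dm = -np.ones((4, 12)) * 1e-12
        with pytest.raises(DegenerateInputError):
            afvc(m, dm)


class TestBaselines:
    def test_sine_pitch_recovered(self, sine_signal):
        mean, sd = baseline_pitch_stats(sine_signal)
        assert mean == pytest.approx(200.0, abs=5.0)
        assert sd < 2.0

    def test_swept_tone_has_larger_pitch_sd(self):
        rate = 22050
        t = np.arange(int(2 * rate)) / rate
        sweep = AudioSignal(
            0.5 * np.sin(2 * np.pi * (150.0 * t + 50.0 * t**2 / 4.0)), rate=rate
        )
        steady = AudioSignal(0.5 * np.sin(2 * np.pi * 200.0 * t), rate=rate)
        assert baseline_pitch_stats(sweep)[1] > baseline_pitch_stats(steady)[1]

    def test_pitch_deterministic(self, sine_signal):
        assert baseline_pitch_stats(sine_signal) == baseline_pitch_stats(sine_signal)

    def test_unvoiced_input_rejected(self, rng):
        noise = AudioSignal(rng.normal(0, 0.1, size=22050), rate=22050)
        with pytest.raises(ValueError):
            baseline_pitch_stats(noise, voicing_threshold=0.99)

    def test_intensity_stats_constant(self):
        mean, lo, hi, sd = baseline_intensity_stats(IntensityTrack(np.full(8, 2.0)))
        assert (mean, lo, hi, sd) == (2.0, 2.0, 2.0, 0.0)

    def test_intensity_stats_values_and_permutation(self, rng):
        track = np.array([1.0, 2.0, 3.0, 4.0])
        mean, lo, hi, sd = baseline_intensity_stats(IntensityTrack(track))
        assert (mean, lo, hi) == (2.5, 1.0, 4.0)
        assert sd == pytest.approx(np.std(track, ddof=1))
        shuffled = rng.permutation(track)
        assert baseline_intensity_stats(IntensityTrack(shuffled)) == (mean, lo, hi, sd)
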