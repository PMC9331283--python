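"""Synthetic-cohort generator tests: determinism, construction guarantees."""
from __future__ import annotations

import numpy as np
import pytest

from readtask.audio import frame_signal, intensity_means, pivd
from readtask.datatypes import FrameParams, ReadingMeta
from readtask.head import binarize_rr, count_rotations, head_trajectory, rhr, uhd
from readtask.mouth import mar_sequence, stft_segments
from readtask.synthetic import (
    AudioParams,
    CohortSpec,
    LandmarkParams,
    swapped_spec,
    synth_audio,
    synth_cohort,
    synth_landmarks,
)


class TestSynthAudio:
    def test_deterministic_under_seed(self):
        p = AudioParams(am_depth=0.4)
        a = synth_audio(p, 2.0, 22050, seed=9)
        b = synth_audio(p, 2.0, 22050, seed=9)
        assert np.array_equal(a.samples, b.samples)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            AudioParams(am_depth=-0.1)

    def test_zero_depth_constant_envelope_pivd(self):
        # period-aligned framing: at 200 Hz and 44.1 kHz two periods are
        # exactly 441 samples, so hop 441 / frame 882 samples make every
        # frame of the unmodulated periodic tone sample-identical
        rate = 44100
        quiet = AudioParams(am_depth=0.0, pitch_mod_depth=0.0, spectral_contrast=1.0)
        loud = AudioParams(am_depth=0.5, pitch_mod_depth=0.0, spectral_contrast=1.0)
        params = FrameParams(frame_len=882, hop=441)
        flat = pivd(intensity_means(frame_signal(synth_audio(quiet, 4.0, rate, 1), params)))
        mod = pivd(intensity_means(frame_signal(synth_audio(loud, 4.0, rate, 1), params)))
        assert flat <= 1e-6 * mod

    def test_depth_monotonicity_over_seeds(self):
        params = FrameParams.from_seconds(22050)
        wins = 0
        for seed in range(20):
            lo = synth_audio(AudioParams(am_depth=0.2), 3.0, 22050, seed)
            hi = synth_audio(AudioParams(am_depth=0.4), 3.0, 22050, seed)
            p_lo = pivd(intensity_means(frame_signal(lo, params)))
            p_hi = pivd(intensity_means(frame_signal(hi, params)))
            wins += p_hi > p_lo
        assert wins == 20


class TestSynthLandmarks:
    def test_clean_trajectory_recovers_lines_exactly(self):
        p = LandmarkParams(extra_rot_mean=0.0, jitter_sd=0.0, pause_rate=0.0)
        meta = ReadingMeta(6)
        lm, truth = synth_landmarks(p, meta, duration_s=10.0, fps=30.0, seed=4)
        traj = head_trajectory(lm)
        n = count_rotations(binarize_rr(traj.hm_r))
        assert n == truth["n_rotations"] == 6
        assert rhr(n, meta) == 1.0

    def test_zero_jitter_uhd_closed_form(self):
        p = LandmarkParams(extra_rot_mean=0.0, jitter_sd=0.0, pause_rate=0.0)
        meta = ReadingMeta(5)
        lm, truth = synth_landmarks(p, meta, duration_s=10.0, fps=30.0, seed=4)
        traj = head_trajectory(lm)
        assert uhd(traj.hm_u, meta) == pytest.approx(truth["line_step_px"])

    def test_extra_rotations_counted(self):
        p = LandmarkParams(extra_rot_mean=2.0, jitter_sd=0.0, pause_rate=0.0)
        meta = ReadingMeta(4)
        lm, truth = synth_landmarks(p, meta, duration_s=12.0, fps=30.0, seed=8)
        traj = head_trajectory(lm)
        n = count_rotations(binarize_rr(traj.hm_r))
        assert n == truth["n_rotations"] > 4

    def test_fluent_mar_peaks_at_syllable_frequency(self):
        p = LandmarkParams(extra_rot_mean=0.0, jitter_sd=0.0, pause_rate=0.0)
        lm, truth = synth_landmarks(p, ReadingMeta(4), duration_s=10.0, fps=30.0, seed=2)
        seq = mar_sequence(lm)
        freqs, mags = stft_segments(seq)
        nonzero = freqs > 0.5
        for row in mags:
            peak = freqs[nonzero][np.argmax(row[nonzero])]
            assert peak == pytest.approx(truth["syllable_freq_hz"], abs=0.4)

    def test_pauses_drain_syllable_band_energy(self):
        # dysfluent readings lose spectral energy at the syllable frequency
        for seed in range(20):
            energies = {}
            for name, rate in (("fluent", 0.0), ("dysfluent", 0.8)):
                p = LandmarkParams(extra_rot_mean=0.0, jitter_sd=0.2, pause_rate=rate)
                lm, _ = synth_landmarks(p, ReadingMeta(5), 10.0, 30.0, seed=seed)
                freqs, mags = stft_segments(mar_sequence(lm))
                band = (freqs > 3.4) & (freqs < 4.6)
                energies[name] = mags[:, band].mean()
            assert energies["dysfluent"] < energies["fluent"], f"seed {seed}"

    def test_infeasible_timing_rejected(self):
        p = LandmarkParams(extra_rot_mean=0.0, jitter_sd=0.0, pause_rate=0.0)
        with pytest.raises(ValueError, match="infeasible"):
            synth_landmarks(p, ReadingMeta(40), duration_s=3.0, fps=30.0, seed=0)


class TestCohort:
    SMALL = dict(n_per_group=3, segments_per_subject=2, duration_s=4.0, audio_rate=22050)

    def test_default_sizes(self):
        cohort = synth_cohort(CohortSpec(seed=0))
        assert len(cohort.subjects) == 40
        manifest = cohort.manifest()
        assert len(manifest) == 160
        assert manifest["label"].sum() == 80

    def test_identical_seeds_identical_cohorts(self):
        a = synth_cohort(CohortSpec(seed=5, **self.SMALL))
        b = synth_cohort(CohortSpec(seed=5, **self.SMALL))
        assert a.manifest().equals(b.manifest())
        sa = a.subjects[0].segment(0)
        sb = b.subjects[0].segment(0)
        assert np.array_equal(sa.audio.samples, sb.audio.samples)
        assert np.array_equal(sa.landmarks.points, sb.landmarks.points)

    def test_swapping_group_blocks_swaps_directions(self):
        spec = CohortSpec(seed=3, **self.SMALL)
        normal = synth_cohort(spec).manifest()
        swapped = synth_cohort(swapped_spec(spec)).manifest()
        for col in ("true_am_depth", "true_extra_rot_mean", "true_jitter_sd"):
            d1 = (normal[normal.label == 0][col].median()
                  - normal[normal.label == 1][col].median())
            d2 = (swapped[swapped.label == 0][col].median()
                  - swapped[swapped.label == 1][col].median())
            assert np.sign(d1) == -np.sign(d2) != 0
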