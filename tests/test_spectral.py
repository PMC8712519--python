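"""Spectrogram, tonality, contour extraction and acoustic features."""
import dataclasses

import numpy as np
import pytest

from usvpipe.core import AudioClip, DetectionBox
from usvpipe.pipeline import annotation_box
from usvpipe.spectral import (
    Contour,
    compute_spectrogram,
    extract_contour,
    extract_features,
    frame_tonalities,
    tonality,
)
from usvpipe.synth import synth_call

from conftest import SAMPLE_RATE, make_chirp, make_tone


def box(t0, t1, f0, f1):
    return DetectionBox(t0, t1, f0, f1, 1.0, "test")


class TestSpectrogram:
    def test_tone_peaks_in_correct_bin(self):
        sg = compute_spectrogram(make_tone(25_000))
        bin_w = sg.bin_freqs[1] - sg.bin_freqs[0]
        assert bin_w <= 500.0  # default resolution contract
        peaks = sg.bin_freqs[sg.magnitudes.argmax(axis=0)]
        assert np.all(np.abs(peaks - 25_000) <= bin_w)

    def test_silence_gives_zero_magnitudes(self):
        sg = compute_spectrogram(AudioClip(np.zeros(8192), SAMPLE_RATE))
        assert np.all(sg.magnitudes == 0)

    def test_chirp_peak_bin_monotone(self):
        sg = compute_spectrogram(make_chirp(10_000, 40_000, duration=1.0))
        peaks = sg.bin_freqs[sg.magnitudes.argmax(axis=0)]
        diffs = np.diff(peaks)
        assert np.all(diffs >= 0)
        assert peaks[-1] > peaks[0] + 25_000

    def test_input_validation(self):
        clip = make_tone(20_000, duration=0.001)
        with pytest.raises(ValueError):
            compute_spectrogram(clip, window_length=0.01)  # clip < one window
        with pytest.raises(ValueError):
            compute_spectrogram(make_tone(20_000), overlap=1.0)
        with pytest.raises(ValueError):
            compute_spectrogram(make_tone(20_000), window_length=1e-5)


class TestTonality:
    def test_line_spectrum_is_tonal(self):
        sg = compute_spectrogram(make_tone(25_000))
        score = tonality(sg, sg.n_frames // 2, (5_000, 50_000))
        assert score > 0.9

    def test_flat_spectrum_scores_zero(self):
        sg = compute_spectrogram(make_tone(25_000))
        flat = dataclasses.replace(
            sg, magnitudes=np.ones_like(sg.magnitudes))
        assert tonality(flat, 0, (5_000, 50_000)) == pytest.approx(0.0, abs=1e-9)

    def test_gain_invariance(self):
        sg = compute_spectrogram(make_tone(25_000))
        scaled = dataclasses.replace(sg, magnitudes=sg.magnitudes * 7.3)
        i = sg.n_frames // 2
        assert tonality(sg, i, (5_000, 50_000)) == pytest.approx(
            tonality(scaled, i, (5_000, 50_000)), abs=1e-9
        )

    def test_white_noise_is_mid_range(self):
        rng = np.random.default_rng(0)
        sg = compute_spectrogram(AudioClip(rng.standard_normal(96_000) * 0.05,
                                           SAMPLE_RATE))
        scores = frame_tonalities(sg, (5_000, 50_000))
        # finite-frame flatness estimator bias puts white noise near 0.43
        assert 0.3 < scores.mean() < 0.55

    def test_empty_band_rejected(self):
        sg = compute_spectrogram(make_tone(25_000))
        with pytest.raises(ValueError):
            tonality(sg, 0, (20_000, 20_001))


class TestContour:
    def test_tone_contour_flat_no_frames_dropped(self):
        sg = compute_spectrogram(make_tone(25_000, duration=0.2))
        c = extract_contour(sg, box(0.0, 0.2, 20_000, 30_000), 0.3)
        assert len(c) == sg.n_frames
        bin_w = sg.bin_freqs[1] - sg.bin_freqs[0]
        assert np.all(np.abs(c.peak_freq - 25_000) <= bin_w)

    def test_noise_region_empties_at_half_floor(self):
        rng = np.random.default_rng(1)
        sg = compute_spectrogram(AudioClip(rng.standard_normal(96_000) * 0.05,
                                           SAMPLE_RATE))
        # white-noise frames measure ~0.43 tonality (estimator bias), so a
        # 0.5 floor drops nearly everything and 0.65 empties the contour
        c = extract_contour(sg, box(0.0, 0.5, 5_000, 50_000), 0.5)
        assert len(c) <= 0.15 * sg.n_frames
        assert extract_contour(sg, box(0.0, 0.5, 5_000, 50_000), 0.65).is_empty

    def test_silent_gap_frames_dropped(self):
        a = make_tone(25_000, duration=0.1)
        gap = AudioClip(np.zeros(int(0.05 * SAMPLE_RATE)), SAMPLE_RATE)
        b = make_tone(25_000, duration=0.1)
        clip = AudioClip(np.concatenate([a.samples, gap.samples, b.samples]),
                         SAMPLE_RATE)
        sg = compute_spectrogram(clip)
        c = extract_contour(sg, box(0.0, 0.25, 20_000, 30_000), 0.3)
        assert 0 < len(c) < sg.n_frames
        assert np.all(np.diff(c.times) > 0)

    def test_box_outside_extent_rejected(self):
        sg = compute_spectrogram(make_tone(25_000, duration=0.1))
        with pytest.raises(ValueError):
            extract_contour(sg, box(5.0, 6.0, 20_000, 30_000))


class TestFeatures:
    def test_flat_contour_features(self):
        sg = compute_spectrogram(make_tone(25_000, duration=0.5))
        fv = extract_features(extract_contour(sg, box(0.0, 0.5, 20_000, 30_000)))
        assert fv.slope == pytest.approx(0.0, abs=2_000)
        assert fv.sinuosity == pytest.approx(1.0, abs=0.05)
        assert fv.bandwidth <= 2 * (sg.bin_freqs[1] - sg.bin_freqs[0])
        assert fv.pf_min <= fv.pf_mean <= fv.pf_max

    def test_chirp_slope_closed_form(self):
        sg = compute_spectrogram(make_chirp(10_000, 40_000, duration=1.0))
        fv = extract_features(extract_contour(sg, box(0.0, 1.0, 5_000, 50_000)))
        assert fv.slope == pytest.approx(30_000.0, rel=0.05)

    def test_sinusoidal_fm_contour_is_sinuous(self):
        rate = SAMPLE_RATE
        n = int(0.5 * rate)
        t = np.arange(n) / rate
        freqs = 25_000 + 5_000 * np.sin(2 * np.pi * 40 * t)
        phase = 2 * np.pi * np.cumsum(freqs) / rate
        sg = compute_spectrogram(AudioClip(0.7 * np.sin(phase), rate))
        c = extract_contour(sg, box(0.0, 0.5, 5_000, 50_000))
        fv = extract_features(c)
        # independent brute-force path/chord ratio on the extracted contour
        path = np.sum(np.hypot(np.diff(c.times), np.diff(c.peak_freq)))
        chord = np.hypot(c.times[-1] - c.times[0], c.peak_freq[-1] - c.peak_freq[0])
        assert fv.sinuosity == pytest.approx(path / chord, rel=1e-9)
        assert fv.sinuosity > 1.5

    def test_single_frame_contour_degenerates(self):
        c = Contour(times=np.array([0.1]), peak_freq=np.array([20_000.0]),
                    peak_amp=np.array([1.0]), tonality=np.array([0.9]),
                    hop=0.00133)
        fv = extract_features(c)
        assert fv.duration == pytest.approx(0.00133)
        assert fv.slope == 0.0 and fv.sinuosity == 1.0

    def test_empty_contour_rejected(self):
        c = Contour(times=np.array([]), peak_freq=np.array([]),
                    peak_amp=np.array([]), tonality=np.array([]), hop=0.001)
        with pytest.raises(ValueError):
            extract_features(c)

    def test_feature_extraction_deterministic(self):
        sg = compute_spectrogram(make_chirp(15_000, 30_000, duration=0.3))
        c = extract_contour(sg, box(0.0, 0.3, 5_000, 50_000))
        assert extract_features(c) == extract_features(c)


class TestParameterRecovery:
    @pytest.mark.parametrize(
        "ct,f0,f1",
        [("long_whistle", 24_000.0, 23_000.0),
         ("short_whistle", 22_000.0, 20_500.0),
         ("tsak", 36_000.0, 13_000.0)],
    )
    def test_contour_recovers_generating_trajectory(self, call_types, ct, f0, f1):
        """Contour MAE vs the known generating sweep stays within 2 bin widths."""
        spec = dataclasses.replace(
            call_types[ct],
            f_start_range=(f0, f0), f_end_range=(f1, f1), f_delta_range=(0.0, 0.0),
        )
        clip, ann = synth_call(spec, seed=23)
        sg = compute_spectrogram(clip)
        c = extract_contour(sg, annotation_box(ann), 0.3)
        truth = np.interp(c.times, [0.0, clip.duration], [f0, f1])
        bin_w = sg.bin_freqs[1] - sg.bin_freqs[0]
        mae = np.mean(np.abs(c.peak_freq - truth))
        assert mae <= 2 * bin_w
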