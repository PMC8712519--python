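"""Synthetic call/scene generation: contracts, determinism, energy budget."""
import numpy as np
import pytest
from scipy import signal as sps

from usvpipe.core import BAND_HIGH, BAND_LOW, AudioClip
from usvpipe.synth import (
    SceneSpec,
    apply_attenuation,
    apply_clipping,
    build_experimental_scene,
    build_standardized_file,
    overlay_calls,
    sister_species_variant,
    synth_call,
    synth_series,
)

from conftest import SAMPLE_RATE, make_tone


class TestSynthCall:
    def test_pure_tone_contour_identity(self, call_types):
        """A flat long whistle forced to one frequency peaks in the right bin."""
        import dataclasses

        spec = dataclasses.replace(
            call_types["long_whistle"],
            f_start_range=(25_000.0, 25_000.0),
            f_delta_range=(0.0, 0.0),
        )
        clip, ann = synth_call(spec, seed=0, duration=0.5)
        freqs, _, mags = sps.spectrogram(clip.samples, fs=clip.rate, nperseg=512,
                                         noverlap=256, mode="magnitude")
        active = mags.max(axis=0) > 0.1 * mags.max()
        peak_bins = mags[:, active].argmax(axis=0)
        assert np.all(np.abs(freqs[peak_bins] - 25_000.0) <= freqs[1] - freqs[0])

    def test_trill_syllable_bursts_match_spec(self, call_types):
        """Envelope thresholding finds exactly the requested syllable count."""
        import dataclasses

        spec = dataclasses.replace(call_types["trill"], n_syllables_range=(4, 4))
        clip, ann = synth_call(spec, seed=3)
        env = np.abs(clip.samples)
        w = int(0.002 * clip.rate)
        env = np.convolve(env, np.ones(w) / w, mode="same")
        above = env > 0.1 * env.max()
        bursts = int((np.diff(above.astype(int)) == 1).sum()) + int(above[0])
        assert bursts == 4
        assert ann.duration >= 4 * spec.duration_range[0] + 3 * spec.syllable_gap_range[0]

    def test_same_seed_is_byte_identical(self, call_types):
        a, ann_a = synth_call(call_types["tsak"], seed=11)
        b, ann_b = synth_call(call_types["tsak"], seed=11)
        assert np.array_equal(a.samples, b.samples)
        assert ann_a == ann_b

    def test_rejects_sub_nyquist_rate(self, call_types):
        with pytest.raises(ValueError, match="Nyquist"):
            synth_call(call_types["zip"], seed=0, sample_rate=48_000)

    @pytest.mark.parametrize("ct", ["long_whistle", "trill", "short_whistle", "tsak", "zip"])
    def test_band_confinement_and_annotation_energy(self, call_types, ct):
        """>=99% of call energy in 5-50 kHz; >=90% inside the annotation box."""
        clip, ann = synth_call(call_types[ct], seed=17)
        sos = sps.butter(6, [BAND_LOW, BAND_HIGH], btype="bandpass",
                         fs=clip.rate, output="sos")
        in_band = sps.sosfiltfilt(sos, clip.samples)
        total = np.sum(clip.samples**2)
        assert np.sum(in_band**2) / total >= 0.99
        i0, i1 = int(ann.t_start * clip.rate), int(ann.t_end * clip.rate)
        assert np.sum(clip.samples[i0:i1] ** 2) / total >= 0.90

    def test_series_structure(self, call_types):
        """Three calls per series, intercall intervals below 200 ms."""
        clip, anns = synth_series(call_types["tsak"], seed=5, series_id="s0")
        assert len(anns) == 3
        assert all(a.series_id == "s0" for a in anns)
        for prev, nxt in zip(anns, anns[1:]):
            assert 0 < nxt.t_start - prev.t_end < 0.2


class TestDegradations:
    def test_clipping_noop_below_level(self):
        clip = make_tone(20_000, amp=0.8)
        out = apply_clipping(clip, 1.0)
        assert np.array_equal(out.samples, clip.samples)

    def test_clipping_saturates_unit_sine(self):
        clip = make_tone(20_000, amp=1.0)
        out = apply_clipping(clip, 0.5)
        assert np.max(np.abs(out.samples)) == pytest.approx(0.5)
        frac_at_rail = np.mean(np.abs(out.samples) == 0.5)
        assert frac_at_rail >= 0.10

    def test_clipping_idempotent_and_rejects_nonpositive(self):
        clip = make_tone(22_000, amp=0.9)
        once = apply_clipping(clip, 0.4)
        twice = apply_clipping(once, 0.4)
        assert np.array_equal(once.samples, twice.samples)
        with pytest.raises(ValueError):
            apply_clipping(clip, 0.0)

    @pytest.mark.parametrize(
        "gain_db,expected_ratio,tol",
        [(0.0, 1.0, 1e-12), (-20.0, 0.1, 1e-9), (-6.0206, 0.5, 1e-4)],
    )
    def test_attenuation_closed_form(self, gain_db, expected_ratio, tol):
        clip = make_tone(25_000, amp=0.6)
        out = apply_attenuation(clip, gain_db)
        assert out.rms / clip.rms == pytest.approx(expected_ratio, abs=tol)


class TestOverlay:
    def test_overlay_with_silence_is_identity(self):
        clip = make_tone(20_000)
        silence = AudioClip(np.zeros_like(clip.samples), clip.rate)
        out = overlay_calls(clip, silence, 0.0)
        assert np.allclose(out.samples, clip.samples)

    def test_self_overlay_doubles(self):
        clip = make_tone(20_000)
        out = overlay_calls(clip, clip, 0.0)
        assert np.allclose(out.samples, 2 * clip.samples)

    def test_full_overlap_shows_two_ridges(self):
        """Two simultaneous tones give two per-frame spectral peaks."""
        a, b = make_tone(20_000), make_tone(35_000)
        out = overlay_calls(a, b, 0.0)
        freqs, _, mags = sps.spectrogram(out.samples, fs=out.rate, nperseg=512,
                                         noverlap=256, mode="magnitude")
        lower = (freqs > 15_000) & (freqs < 25_000)
        upper = (freqs > 30_000) & (freqs < 40_000)
        bin_w = freqs[1] - freqs[0]
        for frame in mags[:, 5:-5].T:
            assert abs(freqs[lower][frame[lower].argmax()] - 20_000) <= bin_w
            assert abs(freqs[upper][frame[upper].argmax()] - 35_000) <= bin_w

    def test_zero_overlap_rejected(self):
        a, b = make_tone(20_000, duration=0.1), make_tone(30_000, duration=0.1)
        with pytest.raises(ValueError, match="outside"):
            overlay_calls(a, b, 0.5)


class TestScenes:
    def test_standardized_layout_and_counts(self, call_types):
        """50 long-whistle units -> 50 annotations and 51 separators of 3 s."""
        spec = SceneSpec(kind="standardized", calls=(("long_whistle", 50),), seed=9)
        clip, anns = build_standardized_file(spec)
        assert len(anns) == 50
        total_call = sum(a.duration for a in anns)
        assert clip.duration >= 51 * 3.0 + total_call - 1.0
        assert anns == sorted(anns, key=lambda a: a.t_start)

    def test_series_units_give_three_calls_each(self, call_types):
        spec = SceneSpec(kind="standardized", calls=(("tsak", 10),), seed=4)
        _, anns = build_standardized_file(spec)
        assert len(anns) == 30
        assert len({a.series_id for a in anns}) == 10

    def test_empty_call_list_rejected(self):
        with pytest.raises(ValueError):
            build_standardized_file(SceneSpec(kind="standardized", calls=(), seed=0))

    def test_overlaid_scenario_cross_links(self):
        spec = SceneSpec(kind="standardized", scenario="overlaid",
                         calls=(("long_whistle", 4),), seed=6)
        _, anns = build_standardized_file(spec)
        by_id = {a.id: a for a in anns}
        linked = [a for a in anns if a.overlaid_with is not None]
        assert len(linked) == 8  # 4 targets + 4 partners
        for a in linked:
            partner = by_id[a.overlaid_with]
            assert partner.overlaid_with == a.id
            assert max(a.t_start, partner.t_start) < min(a.t_end, partner.t_end)
            assert partner.call_type != a.call_type

    def test_experimental_scene_disjoint_and_deterministic(self):
        spec = SceneSpec(
            kind="experimental",
            calls=tuple((ct, 5) for ct in
                        ("long_whistle", "trill", "short_whistle", "tsak", "zip")),
            noise_events=10, seed=12,
        )
        clip, anns = build_experimental_scene(spec)
        calls = [a for a in anns if not a.is_noise]
        noise = [a for a in anns if a.is_noise]
        assert len(calls) == 25 and len(noise) == 10
        non_series = [a for a in calls if a.series_id is None] + noise
        for i, a in enumerate(non_series):
            for b in non_series[i + 1:]:
                assert min(a.t_end, b.t_end) <= max(a.t_start, b.t_start)
        clip2, anns2 = build_experimental_scene(spec)
        assert np.array_equal(clip.samples, clip2.samples)
        assert anns == anns2

    def test_noise_free_scene_has_only_calls(self):
        spec = SceneSpec(kind="experimental", calls=(("zip", 3),), seed=2)
        _, anns = build_experimental_scene(spec)
        assert all(not a.is_noise for a in anns)


class TestSisterSpecies:
    def test_variant_has_two_syllables_and_is_idempotent(self, call_types):
        variant = sister_species_variant(call_types["trill"])
        assert variant.n_syllables_range == (2, 2)
        assert variant.syllable_gap_range[0] > call_types["trill"].syllable_gap_range[0]
        assert sister_species_variant(variant) == variant

    def test_non_trill_rejected(self, call_types):
        with pytest.raises(ValueError):
            sister_species_variant(call_types["zip"])
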