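"""Duration-stratified call-candidate detection in the 5--50 kHz band.

Three detector profiles mirror the duration structure of the repertoire:
*long* (Long whistle, Trill), *short* (Short whistle, Tsak) and
*very short* (Zip).  Each profile runs the same deterministic segmentation:
smoothed in-band peak-bin energy must exceed a threshold above the
per-file noise floor while the frame tonality passes the profile's gate;
surviving segments are kept only inside the profile's duration window.

This is a deterministic spectrogram-energy/tonality segmenter with the
same observable failure modes a learned box detector shows on this
material -- call fragments, series clustered into one box, trill syllables
reported as separate short calls -- which is exactly what the downstream
filtering stages exist to repair.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import BAND_HIGH, BAND_LOW, DetectionBox
from .spectral import Spectrogram, _band_tonalities

_EPS = 1e-30

#: Power floor (dB below segment peak) defining a box's frequency support.
_FREQ_SUPPORT_DB = 25.0


@dataclass(frozen=True)
class DetectorProfile:
    """Segmentation parameters for one duration class."""

    name: str
    min_duration: float
    max_duration: float
    smoothing_window: float
    energy_threshold: float = 8.0  # dB above the per-file noise floor
    band: Tuple[float, float] = (BAND_LOW, BAND_HIGH)
    min_tonality: float = 0.3

    def __post_init__(self) -> None:
        if not self.min_duration < self.max_duration:
            raise ValueError("profile requires min_duration < max_duration")


def default_profiles() -> Dict[str, DetectorProfile]:
    """The three stock profiles (duration gates are package defaults).

    The tonality gates step up as the duration gate shrinks: very short
    segments offer few frames of evidence, so they must be strongly tonal
    to count, which keeps single-frame noise excursions out of the
    very-short detector while the long/short detectors still pick up
    broadband transients (handled later by the denoiser).
    """
    return {
        "long": DetectorProfile(
            name="long", min_duration=0.15, max_duration=3.0,
            smoothing_window=0.05, min_tonality=0.30,
        ),
        "short": DetectorProfile(
            name="short", min_duration=0.02, max_duration=0.2,
            smoothing_window=0.01, min_tonality=0.35,
        ),
        "very_short": DetectorProfile(
            name="very_short", min_duration=0.004, max_duration=0.03,
            smoothing_window=0.003, min_tonality=0.55,
        ),
    }


def detect(spec: Spectrogram, profile: DetectorProfile) -> List[DetectionBox]:
    """Candidate boxes for one profile, sorted by start time.

    The per-frame statistic is the maximum in-band bin power in dB (matched
    to narrowband calls), smoothed over the profile's smoothing window; the
    noise floor is the per-file median of that smoothed statistic.  Segments
    separated by gaps shorter than one smoothing window are fused before the
    duration gate; each surviving box's frequency bounds are tightened to
    its energy support and its score is the mean frame tonality.
    """
    fsl = spec.band_slice(*profile.band)
    mags = spec.magnitudes[fsl, :].astype(np.float64)
    power = mags**2
    stat_db = 10.0 * np.log10(power.max(axis=0) + _EPS)
    w = max(1, int(round(profile.smoothing_window / spec.hop)))
    smoothed = uniform_filter1d(stat_db, size=w, mode="nearest")
    floor = float(np.median(smoothed))
    ton = _band_tonalities(mags)
    mask = (smoothed >= floor + profile.energy_threshold) & (ton >= profile.min_tonality)

    segments = _fuse_segments(_mask_to_segments(mask), max_gap=w)
    band_freqs = spec.bin_freqs[fsl]
    bin_width = float(band_freqs[1] - band_freqs[0]) if band_freqs.size > 1 else 100.0
    boxes: List[DetectionBox] = []
    for i0, i1 in segments:  # i1 inclusive
        t_start = spec.frame_times[i0] - spec.hop / 2
        t_end = spec.frame_times[i1] + spec.hop / 2
        dur = t_end - t_start
        if not profile.min_duration <= dur <= profile.max_duration:
            continue
        seg_power = power[:, i0 : i1 + 1].max(axis=1)
        support = np.nonzero(seg_power >= seg_power.max() * 10 ** (-_FREQ_SUPPORT_DB / 10))[0]
        f_low = max(profile.band[0], band_freqs[support[0]] - bin_width / 2)
        f_high = min(profile.band[1], band_freqs[support[-1]] + bin_width / 2)
        boxes.append(
            DetectionBox(
                t_start=float(t_start),
                t_end=float(t_end),
                f_low=float(f_low),
                f_high=float(f_high),
                score=float(np.clip(ton[i0 : i1 + 1].mean(), 0.0, 1.0)),
                source_detector=profile.name,
            )
        )
    return boxes


def multi_detect(
    spec: Spectrogram, profiles: Sequence[DetectorProfile]
) -> List[DetectionBox]:
    """All profiles run side by side; plain concatenation of their outputs.

    Duplicates and doublet syllables are deliberately kept -- removing them
    is the post-filter's job.
    """
    out: List[DetectionBox] = []
    for profile in profiles:
        out.extend(detect(spec, profile))
    return out


def _mask_to_segments(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Contiguous True runs as (first, last) inclusive frame indices."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.nonzero(padded == 1)[0]
    ends = np.nonzero(padded == -1)[0] - 1
    return list(zip(starts.tolist(), ends.tolist()))


def _fuse_segments(
    segments: List[Tuple[int, int]], max_gap: int
) -> List[Tuple[int, int]]:
    """Fuse segments whose separating gap is shorter than ``max_gap`` frames."""
    if not segments:
        return []
    fused = [segments[0]]
    for s, e in segments[1:]:
        ps, pe = fused[-1]
        if s - pe - 1 < max_gap:
            fused[-1] = (ps, e)
        else:
            fused.append((s, e))
    return fused


__all__ = ["DetectorProfile", "default_profiles", "detect", "multi_detect"]
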