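"""Spectrogram computation, contour detection and acoustic features.

The measurement core shared by every downstream model.  A call's *contour*
is the per-frame frequency at maximum amplitude inside a time--frequency
box, cleaned by removing non-tonal frames.  Tonality is defined as
``1 - spectral flatness`` of the in-band power spectrum: 0 for an exactly
flat spectrum, approaching 1 for a line spectrum.  Note that a *finite*
white-noise frame has tonality around 0.4 (the single-frame flatness
estimator is biased below 1), well separated from the > 0.9 tonality of
clean tonal calls.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal as _signal

from .core import BAND_HIGH, BAND_LOW, AcousticFeatureVector, AudioClip, DetectionBox

#: Default analysis window in samples (~2.7 ms at 192 kHz) and overlap.
DEFAULT_WINDOW_SAMPLES = 512
DEFAULT_OVERLAP = 0.5

#: Default per-frame tonality floor used when cleaning contours.
DEFAULT_TONALITY_FLOOR = 0.3

_EPS = 1e-30


@dataclass(frozen=True)
class Spectrogram:
    """Magnitude short-time spectrum: ``magnitudes[bin, frame]``."""

    magnitudes: np.ndarray
    frame_times: np.ndarray
    bin_freqs: np.ndarray
    window_length: float
    hop: float

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[1]

    def band_slice(self, f_low: float, f_high: float) -> slice:
        """Index slice of the bins whose centres lie in ``[f_low, f_high]``."""
        lo = int(np.searchsorted(self.bin_freqs, f_low, side="left"))
        hi = int(np.searchsorted(self.bin_freqs, f_high, side="right"))
        if hi <= lo:
            raise ValueError("empty frequency band")
        return slice(lo, hi)

    def time_slice(self, t_start: float, t_end: float) -> slice:
        lo = int(np.searchsorted(self.frame_times, t_start, side="left"))
        hi = int(np.searchsorted(self.frame_times, t_end, side="right"))
        return slice(lo, hi)


@dataclass(frozen=True)
class Contour:
    """Cleaned peak-frequency trajectory of one detection."""

    times: np.ndarray
    peak_freq: np.ndarray
    peak_amp: np.ndarray
    tonality: np.ndarray
    hop: float

    def __len__(self) -> int:
        return self.times.size

    @property
    def is_empty(self) -> bool:
        return self.times.size == 0


def compute_spectrogram(
    clip: AudioClip,
    window_length: Optional[float] = None,
    overlap: float = DEFAULT_OVERLAP,
) -> Spectrogram:
    """Magnitude spectrogram of a clip.

    ``window_length`` is in seconds (default 512 samples at the clip rate);
    ``overlap`` is the fractional window overlap in [0, 1).
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    if window_length is None:
        n_win = DEFAULT_WINDOW_SAMPLES
    else:
        n_win = int(round(window_length * clip.rate))
    if n_win < 8:
        raise ValueError("window must span at least 8 samples")
    if clip.samples.size < n_win:
        raise ValueError("clip shorter than one analysis window")
    hop = max(1, int(round(n_win * (1.0 - overlap))))
    # spectrogram() keeps every analysis window fully inside the signal,
    # so frame times are exact window centres
    freqs, times, mags = _signal.spectrogram(
        clip.samples.astype(np.float32),
        fs=clip.rate,
        window=("hann",),
        nperseg=n_win,
        noverlap=n_win - hop,
        mode="magnitude",
        detrend=False,
    )
    return Spectrogram(
        magnitudes=mags.astype(np.float32),
        frame_times=times,
        bin_freqs=freqs,
        window_length=n_win / clip.rate,
        hop=hop / clip.rate,
    )


def tonality(spec: Spectrogram, frame_index: int, band: Tuple[float, float]) -> float:
    """Per-frame tonality: ``1 - spectral flatness`` of in-band power."""
    sl = spec.band_slice(*band)
    power = spec.magnitudes[sl, frame_index].astype(np.float64) ** 2
    return _tonality_of_power(power)


def _tonality_of_power(power: np.ndarray) -> float:
    amean = power.mean()
    if amean <= _EPS:
        return 0.0  # silent frame: treated as non-tonal
    gmean = np.exp(np.mean(np.log(power + _EPS * amean)))
    return float(np.clip(1.0 - gmean / amean, 0.0, 1.0))


def frame_tonalities(spec: Spectrogram, band: Tuple[float, float]) -> np.ndarray:
    """Vectorized tonality for every frame (same definition as :func:`tonality`)."""
    sl = spec.band_slice(*band)
    power = spec.magnitudes[sl, :].astype(np.float64) ** 2
    amean = power.mean(axis=0)
    safe = np.maximum(amean, _EPS)
    gmean = np.exp(np.mean(np.log(power + _EPS * safe[None, :]), axis=0))
    out = np.clip(1.0 - gmean / safe, 0.0, 1.0)
    out[amean <= _EPS] = 0.0
    return out


def extract_contour(
    spec: Spectrogram,
    box: DetectionBox,
    tonality_floor: float = DEFAULT_TONALITY_FLOOR,
) -> Contour:
    """Peak-frequency contour inside a box, dropping non-tonal frames.

    Per frame inside the box's time extent, the peak frequency and amplitude
    are taken over the box's frequency band (lowest bin wins ties); frames
    whose tonality falls below ``tonality_floor`` are removed.  Tonality is
    judged over the whole analysis band, not the (often few-bin-narrow) box
    band, so a clean tone reads as tonal and a noise frame as flat.  An
    empty contour is a valid result.
    """
    tsl = spec.time_slice(box.t_start, box.t_end)
    if tsl.stop <= tsl.start:
        raise ValueError("box lies outside the spectrogram's time extent")
    fsl = spec.band_slice(box.f_low, box.f_high)
    mags = spec.magnitudes[fsl, tsl].astype(np.float64)
    ton_lo = max(BAND_LOW, float(spec.bin_freqs[0]))
    ton_hi = min(BAND_HIGH, float(spec.bin_freqs[-1]))
    try:
        ton_slice = spec.band_slice(ton_lo, ton_hi)
    except ValueError:  # spectrogram entirely outside the analysis band
        ton_slice = slice(None)
    ton = _band_tonalities(spec.magnitudes[ton_slice, tsl].astype(np.float64))
    peak_idx = mags.argmax(axis=0)  # argmax returns the lowest index among ties
    keep = ton >= tonality_floor
    return Contour(
        times=spec.frame_times[tsl][keep],
        peak_freq=spec.bin_freqs[fsl][peak_idx][keep],
        peak_amp=mags[peak_idx, np.arange(mags.shape[1])][keep],
        tonality=ton[keep],
        hop=spec.hop,
    )


def _band_tonalities(mags: np.ndarray) -> np.ndarray:
    power = mags**2
    amean = power.mean(axis=0)
    safe = np.maximum(amean, _EPS)
    gmean = np.exp(np.mean(np.log(power + _EPS * safe[None, :]), axis=0))
    out = np.clip(1.0 - gmean / safe, 0.0, 1.0)
    out[amean <= _EPS] = 0.0
    return out


def extract_features(contour: Contour) -> AcousticFeatureVector:
    """Temporal, spectral and tonality parameters of a non-empty contour.

    Duration spans the contour frames; the slope is the ordinary
    least-squares trend of (time, peak frequency); sinuosity is the contour
    path length over the straight chord in the time--frequency plane.  A
    single-frame contour degenerates to ``duration = hop``, slope 0,
    sinuosity 1.
    """
    if contour.is_empty:
        raise ValueError("cannot extract features from an empty contour")
    t = contour.times
    f = contour.peak_freq
    if t.size == 1:
        return AcousticFeatureVector(
            duration=contour.hop,
            pf_mean=float(f[0]),
            pf_min=float(f[0]),
            pf_max=float(f[0]),
            pf_start=float(f[0]),
            pf_end=float(f[0]),
            bandwidth=0.0,
            slope=0.0,
            sinuosity=1.0,
            tonality_mean=float(contour.tonality[0]),
            n_syllable_estimate=1,
        )
    duration = float(t[-1] - t[0] + contour.hop)
    slope = float(np.polyfit(t, f, 1)[0])
    path = float(np.sum(np.hypot(np.diff(t), np.diff(f))))
    chord = float(np.hypot(t[-1] - t[0], f[-1] - f[0]))
    sinuosity = max(1.0, path / chord) if chord > 0 else 1.0
    return AcousticFeatureVector(
        duration=duration,
        pf_mean=float(f.mean()),
        pf_min=float(f.min()),
        pf_max=float(f.max()),
        pf_start=float(f[0]),
        pf_end=float(f[-1]),
        bandwidth=float(f.max() - f.min()),
        slope=slope,
        sinuosity=sinuosity,
        tonality_mean=float(contour.tonality.mean()),
        n_syllable_estimate=_count_syllables(contour),
    )


def _count_syllables(contour: Contour, rel_threshold: float = 0.1) -> int:
    """Energy bursts along the contour, the syllable-count estimate.

    The contour is split wherever consecutive frames are separated by more
    than two hops (frames removed by tonality cleaning leave such time
    gaps); within each piece, contiguous runs of frames whose amplitude
    exceeds ``rel_threshold`` of the contour peak are counted, with
    single-frame dropouts bridged.  This recovers the syllable count of
    gap-separated multi-syllable calls such as the trill.
    """
    amp_max = contour.peak_amp.max()
    pieces = np.split(
        np.arange(contour.times.size),
        np.nonzero(np.diff(contour.times) > 2.0 * contour.hop)[0] + 1,
    )
    total = 0
    for piece in pieces:
        above = contour.peak_amp[piece] > rel_threshold * amp_max
        if above.size >= 3:  # bridge isolated single-frame dropouts
            mid = ~above[1:-1] & above[:-2] & above[2:]
            above[1:-1] |= mid
        edges = np.diff(above.astype(int))
        total += int((edges == 1).sum()) + int(above[0])
    return max(1, total)


__all__ = [
    "Spectrogram",
    "Contour",
    "compute_spectrogram",
    "tonality",
    "frame_tonalities",
    "extract_contour",
    "extract_features",
    "DEFAULT_WINDOW_SAMPLES",
    "DEFAULT_OVERLAP",
    "DEFAULT_TONALITY_FLOOR",
]
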