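"""Shared domain types for the vocalization-analysis pipeline.

The analysis band is 5--50 kHz: the high-frequency/ultrasonic part of the
adult gray mouse lemur (*Microcebus murinus*) repertoire.  Everything below
5 kHz (Grunts, Croaks) is outside the band of interest and is not modelled.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Lower / upper edge of the analysis band in Hz.
BAND_LOW = 5_000.0
BAND_HIGH = 50_000.0

#: The five modelled call types of the adult repertoire, ordered long to short.
CALL_TYPES = ("long_whistle", "trill", "short_whistle", "tsak", "zip")

#: Label used for annotated non-call transients (scratching/digging proxies).
NOISE_LABEL = "noise"


@dataclass(frozen=True)
class AudioClip:
    """A mono sampled waveform; the unit every pipeline stage consumes."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioClip is mono: samples must be 1-D")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def rms(self) -> float:
        if self.samples.size == 0:
            return 0.0
        return float(np.sqrt(np.mean(self.samples**2)))


@dataclass
class CallAnnotation:
    """Ground-truth time/frequency box for one call (or noise event).

    Times are seconds from file start, half-open interval ``[t_start, t_end)``.
    ``series_id`` groups the members of a rapid call series (Tsak /
    Short whistle, intercall interval < 200 ms).  ``overlaid_with`` holds the
    id of a temporally superimposed partner call in the overlaid scenario.
    """

    t_start: float
    t_end: float
    f_low: float
    f_high: float
    call_type: str
    series_id: Optional[str] = None
    scenario: str = "good"
    overlaid_with: Optional[str] = None
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("annotation requires t_start < t_end")
        if not self.f_low < self.f_high:
            raise ValueError("annotation requires f_low < f_high")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def is_noise(self) -> bool:
        return self.call_type == NOISE_LABEL


#: Lifecycle states of a detection box as it moves through the pipeline.
BOX_STATUSES = ("raw", "filtered", "accepted", "rejected", "adjusted")


@dataclass
class DetectionBox:
    """A detected time--frequency rectangle ("measuring box")."""

    t_start: float
    t_end: float
    f_low: float
    f_high: float
    score: float
    source_detector: str
    label: Optional[str] = None
    status: str = "raw"

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("box requires t_start < t_end")
        if not self.f_low < self.f_high:
            raise ValueError("box requires f_low < f_high")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("box score must lie in [0, 1]")
        if self.status not in BOX_STATUSES:
            raise ValueError(f"unknown box status {self.status!r}")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


#: Column order of :meth:`AcousticFeatureVector.to_array`.
FEATURE_NAMES = (
    "duration",
    "pf_mean",
    "pf_min",
    "pf_max",
    "pf_start",
    "pf_end",
    "bandwidth",
    "slope",
    "sinuosity",
    "tonality_mean",
    "n_syllable_estimate",
)

#: Feature-group membership used for equal-weight clustering inputs
#: (frequency-, duration- and contour-derived parameters).
FEATURE_GROUPS = {
    "frequency": ("pf_mean", "pf_min", "pf_max", "pf_start", "pf_end", "bandwidth"),
    "duration": ("duration",),
    "contour": ("slope", "sinuosity", "tonality_mean", "n_syllable_estimate"),
}


@dataclass(frozen=True)
class AcousticFeatureVector:
    """Temporal, spectral and tonality parameters of one call contour.

    ``pf_*`` are peak-frequency statistics in Hz, ``slope`` the
    least-squares trend of the contour in Hz/s, ``sinuosity`` the contour
    path length divided by the straight chord (>= 1), ``tonality_mean`` the
    mean per-frame tonality in [0, 1].
    """

    duration: float
    pf_mean: float
    pf_min: float
    pf_max: float
    pf_start: float
    pf_end: float
    bandwidth: float
    slope: float
    sinuosity: float
    tonality_mean: float
    n_syllable_estimate: int

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("feature duration must be positive")
        if not self.pf_min <= self.pf_mean <= self.pf_max:
            raise ValueError("peak-frequency stats must satisfy min <= mean <= max")
        if self.sinuosity < 1.0 - 1e-9:
            raise ValueError("sinuosity is >= 1 by construction")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


def features_to_matrix(features) -> np.ndarray:
    """Stack feature vectors into an ``(n, len(FEATURE_NAMES))`` matrix."""
    if len(features) == 0:
        return np.empty((0, len(FEATURE_NAMES)))
    return np.vstack([f.to_array() for f in features])


def temporal_iou(a_start: float, a_end: float, b_start: float, b_end: float) -> float:
    """Intersection-over-union of two time intervals (0 when disjoint)."""
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    union = max(a_end, b_end) - min(a_start, b_start)
    return inter / union


def temporal_overlap(a_start: float, a_end: float, b_start: float, b_end: float) -> float:
    """Length of the overlap of two time intervals (0 when disjoint)."""
    return max(0.0, min(a_end, b_end) - max(a_start, b_start))


__all__ = [
    "AudioClip",
    "CallAnnotation",
    "DetectionBox",
    "AcousticFeatureVector",
    "BAND_LOW",
    "BAND_HIGH",
    "CALL_TYPES",
    "NOISE_LABEL",
    "BOX_STATUSES",
    "FEATURE_NAMES",
    "FEATURE_GROUPS",
    "features_to_matrix",
    "temporal_iou",
    "temporal_overlap",
    "replace",
]
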