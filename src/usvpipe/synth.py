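"""Synthetic vocalization scenes with exact ground truth.

Emulates archive-style recordings of the five high-frequency/ultrasonic
call types of the adult gray mouse lemur repertoire (Long whistle, Trill,
Short whistle, Tsak, Zip) inside the 5--50 kHz analysis band:

* **standardized files** -- one call type per file, units separated by 3 s
  of white noise, under four recording-quality scenarios (good, clipped,
  low-amplitude, overlaid);
* **experimental scenes** -- mixed call types at random onsets plus
  broadband noise transients (scratching/digging proxies) over a continuous
  noise bed.

Tsak and Short whistle are emitted in rapid series; a series unit here is
three calls separated by intercall intervals < 200 ms.  Every operation is
deterministic given its spec and seed (bit-identical audio and annotations
on re-run).

The per-type acoustic parametrization (duration/frequency ranges, contour
shapes) is this package's own reconstruction of the repertoire and is fully
configurable; see ``docs/methods.md`` for the values and their motivation.
The Short whistle is deliberately modelled with a shallow descending glide
so that its short-duration tail forms a continuum with the Zip, mirroring
the natural transitions between these types.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as _signal

from .core import (
    BAND_HIGH,
    BAND_LOW,
    CALL_TYPES,
    NOISE_LABEL,
    AudioClip,
    CallAnnotation,
)

#: Default sample rate in Hz.  Any rate >= 100 kHz (twice the band top) works.
DEFAULT_SAMPLE_RATE = 192_000

#: Default white-noise separator level, dBFS RMS.  The source recordings had
#: "28 dB" separator noise with no stated reference; here the level is a free
#: parameter referenced to full scale.
DEFAULT_SEPARATOR_NOISE_DB = -28.0

#: Default degradation parameters for the quality scenarios.
DEFAULT_CLIP_LEVEL = 0.5
#: Low-amplitude scenario gain.  Good-quality calls sit ~35-40 dB above the
#: detector's noise floor; -20 dB leaves weak but present contours (a
#: fragmenting, partly recoverable regime) rather than erasing the calls.
DEFAULT_ATTENUATION_DB = -20.0

#: Overlay partner for each call type in the overlaid scenario (two calls of
#: different types superimposed).  Zips are not degraded (good-quality only).
OVERLAY_PARTNERS = {
    "long_whistle": "trill",
    "trill": "long_whistle",
    "short_whistle": "tsak",
    "tsak": "short_whistle",
    "zip": "short_whistle",
}

SCENARIOS = ("good", "clipped", "low_amplitude", "overlaid")

#: Margin in seconds kept between placed units in experimental scenes.
_PLACEMENT_MARGIN = 0.12

#: Frequency margin (Hz) added around the contour extent in annotations.
_FREQ_MARGIN = 300.0


@dataclass(frozen=True)
class CallTypeSpec:
    """Acoustic parametrization of one call type.

    ``duration_range`` is the tone duration of a single call, or of one
    syllable for the multi-syllable Trill (whose total duration then emerges
    from the syllable count and gaps).  Frequencies are fundamental peak
    frequencies in Hz; ``f_delta_range`` shifts the contour end relative to
    its start unless an absolute ``f_end_range`` is given.
    """

    name: str
    duration_range: Tuple[float, float]
    f_start_range: Tuple[float, float]
    contour_shape: str  # flat | down_sweep | up_sweep | sinusoidal_fm | multi_syllable
    f_delta_range: Tuple[float, float] = (0.0, 0.0)
    #: Beta(1, shape) skew of the glide magnitude inside ``f_delta_range``:
    #: 1 = uniform; larger values concentrate draws near the second edge of
    #: the range with a rare tail toward the first (used to give the Short
    #: whistle mostly shallow glides plus occasional steep, Zip-like ones).
    f_delta_shape: float = 1.0
    f_end_range: Optional[Tuple[float, float]] = None
    n_syllables_range: Tuple[int, int] = (1, 1)
    syllable_gap_range: Tuple[float, float] = (0.0, 0.0)
    fm_depth_range: Tuple[float, float] = (0.0, 0.0)
    fm_rate_range: Tuple[float, float] = (0.0, 0.0)
    amplitude_envelope: str = "trapezoid"  # trapezoid | hann
    amplitude_range: Tuple[float, float] = (0.55, 0.85)
    series_size: int = 1
    intercall_interval_range: Tuple[float, float] = (0.08, 0.18)

    def __post_init__(self) -> None:
        if self.name not in CALL_TYPES:
            raise ValueError(f"unknown call type {self.name!r}")
        if self.n_syllables_range[1] > 1 and self.name != "trill":
            raise ValueError("only the trill is multi-syllabic")
        if self.series_size not in (1, 3):
            raise ValueError("series_size is 1, or 3 for series call types")
        if self.series_size == 3 and self.intercall_interval_range[1] >= 0.2:
            raise ValueError("intercall intervals of a series must stay < 200 ms")
        if self.amplitude_envelope not in ("trapezoid", "hann"):
            raise ValueError(f"unknown envelope {self.amplitude_envelope!r}")


def default_call_types() -> dict:
    """The package's default parametrization of the five call types."""
    return {
        "long_whistle": CallTypeSpec(
            name="long_whistle",
            duration_range=(0.2, 1.5),
            f_start_range=(13_000.0, 25_000.0),
            f_delta_range=(-2_000.0, 2_000.0),
            contour_shape="flat",
        ),
        "trill": CallTypeSpec(
            name="trill",
            duration_range=(0.08, 0.18),  # per syllable
            f_start_range=(15_000.0, 28_000.0),
            contour_shape="multi_syllable",
            n_syllables_range=(3, 8),
            syllable_gap_range=(0.01, 0.04),
            fm_depth_range=(2_000.0, 6_000.0),
            fm_rate_range=(20.0, 60.0),
        ),
        # The Short whistle grades into neighbouring types: its duration
        # reaches down into the Zip range and its normally shallow glide has
        # a rare steep tail, so the shortest, steepest Short whistles are
        # genuinely Zip-like (the natural transitional forms).
        "short_whistle": CallTypeSpec(
            name="short_whistle",
            duration_range=(0.015, 0.10),
            f_start_range=(18_000.0, 26_000.0),
            f_delta_range=(-8_000.0, 0.0),
            f_delta_shape=5.0,
            contour_shape="flat",
            series_size=3,
        ),
        "tsak": CallTypeSpec(
            name="tsak",
            duration_range=(0.02, 0.08),
            f_start_range=(30_000.0, 40_000.0),
            f_end_range=(10_000.0, 15_000.0),
            contour_shape="down_sweep",
            series_size=3,
        ),
        "zip": CallTypeSpec(
            name="zip",
            duration_range=(0.005, 0.03),
            f_start_range=(20_000.0, 30_000.0),
            f_delta_range=(-10_000.0, -3_000.0),
            contour_shape="down_sweep",
            amplitude_envelope="hann",
        ),
    }


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one rendered audio file with ground truth.

    ``calls`` counts *units* (single calls or whole series) for standardized
    scenes and *individual calls* for experimental scenes, where series call
    types are chunked into series of up to three.
    """

    kind: str  # standardized | experimental
    scenario: str = "good"
    calls: Tuple[Tuple[str, int], ...] = ()
    noise_events: int = 0
    separator_duration: float = 3.0
    separator_noise_db: float = DEFAULT_SEPARATOR_NOISE_DB
    sample_rate: int = DEFAULT_SAMPLE_RATE
    seed: int = 0
    clip_level: float = DEFAULT_CLIP_LEVEL
    attenuation_db: float = DEFAULT_ATTENUATION_DB
    call_types: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.kind not in ("standardized", "experimental"):
            raise ValueError(f"unknown scene kind {self.kind!r}")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        object.__setattr__(self, "calls", tuple((str(t), int(n)) for t, n in self.calls))

    def type_spec(self, name: str) -> CallTypeSpec:
        table = self.call_types if self.call_types is not None else default_call_types()
        return table[name]


def _check_rate(sample_rate: int) -> None:
    if sample_rate < 2 * BAND_HIGH:
        raise ValueError(
            f"sample_rate {sample_rate} Hz is below the Nyquist bound "
            f"{2 * BAND_HIGH:.0f} Hz for the {BAND_HIGH / 1000:.0f} kHz analysis band"
        )


def _envelope(n: int, kind: str) -> np.ndarray:
    if kind == "hann":
        return np.hanning(n)
    # trapezoid: 15% linear rise/fall
    ramp = max(1, int(round(0.15 * n)))
    env = np.ones(n)
    env[:ramp] = np.linspace(0.0, 1.0, ramp, endpoint=False)
    env[n - ramp :] = np.linspace(1.0, 0.0, ramp)
    return env


def _tone(freqs: np.ndarray, env: np.ndarray, sample_rate: int, phase0: float) -> np.ndarray:
    phase = phase0 + 2.0 * np.pi * np.cumsum(freqs) / sample_rate
    return env * np.sin(phase)


def _draw_endpoints(spec: CallTypeSpec, rng: np.random.Generator) -> Tuple[float, float]:
    f0 = rng.uniform(*spec.f_start_range)
    if spec.f_end_range is not None:
        f1 = rng.uniform(*spec.f_end_range)
    else:
        d0, d1 = spec.f_delta_range
        u = rng.beta(1.0, spec.f_delta_shape)  # shape 1 => uniform in the range
        f1 = f0 + d1 + (d0 - d1) * u
    lo, hi = BAND_LOW + _FREQ_MARGIN, BAND_HIGH - _FREQ_MARGIN
    return float(np.clip(f0, lo, hi)), float(np.clip(f1, lo, hi))


def synth_call(
    spec: CallTypeSpec,
    seed,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    duration: Optional[float] = None,
) -> Tuple[AudioClip, CallAnnotation]:
    """Render one call and its tight ground-truth box.

    The instantaneous-frequency contour follows ``spec.contour_shape`` inside
    the type's frequency ranges; the annotation encloses the waveform energy
    above -40 dB of the call peak.  ``duration`` overrides the seeded draw
    (handy for tests); for the multi-syllable trill it sets the per-syllable
    tone duration.
    """
    _check_rate(sample_rate)
    rng = np.random.default_rng(seed)
    amp = rng.uniform(*spec.amplitude_range)

    if spec.contour_shape == "multi_syllable":
        n_syll = int(rng.integers(spec.n_syllables_range[0], spec.n_syllables_range[1] + 1))
        carrier = rng.uniform(*spec.f_start_range)
        depth = rng.uniform(*spec.fm_depth_range)
        rate = rng.uniform(*spec.fm_rate_range)
        pieces: List[np.ndarray] = []
        ftrack: List[np.ndarray] = []
        for k in range(n_syll):
            dur = duration if duration is not None else rng.uniform(*spec.duration_range)
            gap = rng.uniform(*spec.syllable_gap_range)
            fm_phase = rng.uniform(0.0, 2.0 * np.pi)
            phase0 = rng.uniform(0.0, 2.0 * np.pi)
            n = max(8, int(round(dur * sample_rate)))
            t = np.arange(n) / sample_rate
            freqs = carrier + depth * np.sin(2.0 * np.pi * rate * t + fm_phase)
            env = _envelope(n, spec.amplitude_envelope)
            pieces.append(_tone(freqs, env, sample_rate, phase0))
            ftrack.append(freqs)
            if k < n_syll - 1:
                gap_n = max(1, int(round(gap * sample_rate)))
                pieces.append(np.zeros(gap_n))
        wave = amp * np.concatenate(pieces)
        f_all = np.concatenate(ftrack)
    else:
        dur = duration if duration is not None else rng.uniform(*spec.duration_range)
        f0, f1 = _draw_endpoints(spec, rng)
        if spec.contour_shape == "down_sweep" and f1 > f0:
            f0, f1 = f1, f0
        if spec.contour_shape == "up_sweep" and f1 < f0:
            f0, f1 = f1, f0
        phase0 = rng.uniform(0.0, 2.0 * np.pi)
        n = max(8, int(round(dur * sample_rate)))
        freqs = np.linspace(f0, f1, n)
        env = _envelope(n, spec.amplitude_envelope)
        wave = amp * _tone(freqs, env, sample_rate, phase0)
        f_all = freqs

    clip = AudioClip(wave, sample_rate)
    ann = _annotate(clip, f_all, spec.name)
    return clip, ann


def _annotate(clip: AudioClip, freqs: np.ndarray, call_type: str) -> CallAnnotation:
    """Tight box around the energy above -40 dB of the call peak."""
    env = np.abs(clip.samples)
    # smooth the rectified waveform over ~0.5 ms to approximate the envelope
    w = max(1, int(round(5e-4 * clip.rate)))
    env = np.convolve(env, np.ones(w) / w, mode="same")
    thr = env.max() * 10 ** (-40 / 20)
    active = np.nonzero(env > thr)[0]
    t0 = active[0] / clip.rate
    t1 = (active[-1] + 1) / clip.rate
    f_low = max(BAND_LOW, float(freqs.min()) - _FREQ_MARGIN)
    f_high = min(BAND_HIGH, float(freqs.max()) + _FREQ_MARGIN)
    return CallAnnotation(t0, t1, f_low, f_high, call_type)


def synth_series(
    spec: CallTypeSpec,
    seed,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    series_id: Optional[str] = None,
    n_calls: Optional[int] = None,
) -> Tuple[AudioClip, List[CallAnnotation]]:
    """Render a rapid call series (intercall intervals < 200 ms)."""
    _check_rate(sample_rate)
    n_calls = spec.series_size if n_calls is None else n_calls
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_calls + 1)
    rng = np.random.default_rng(children[0])
    pieces: List[np.ndarray] = []
    anns: List[CallAnnotation] = []
    t_cursor = 0.0
    for k in range(n_calls):
        clip, ann = synth_call(spec, children[k + 1], sample_rate)
        pieces.append(clip.samples)
        anns.append(
            dataclasses.replace(
                ann,
                t_start=ann.t_start + t_cursor,
                t_end=ann.t_end + t_cursor,
                series_id=series_id,
            )
        )
        t_cursor += clip.duration
        if k < n_calls - 1:
            ici = rng.uniform(*spec.intercall_interval_range)
            gap_n = max(1, int(round(ici * sample_rate)))
            pieces.append(np.zeros(gap_n))
            t_cursor += gap_n / sample_rate
    return AudioClip(np.concatenate(pieces), sample_rate), anns


# ---------------------------------------------------------------------------
# quality-scenario transforms
# ---------------------------------------------------------------------------

def apply_clipping(clip: AudioClip, clip_level: float) -> AudioClip:
    """Hard-limit all samples to ``±clip_level`` (fraction of full scale)."""
    if clip_level <= 0:
        raise ValueError("clip_level must be positive")
    return AudioClip(np.clip(clip.samples, -clip_level, clip_level), clip.rate)


def apply_attenuation(clip: AudioClip, gain_db: float) -> AudioClip:
    """Scale the waveform by ``10^(gain_db/20)`` (negative = attenuation)."""
    return AudioClip(clip.samples * 10 ** (gain_db / 20.0), clip.rate)


def overlay_calls(a: AudioClip, b: AudioClip, offset: float) -> AudioClip:
    """Superimpose ``b`` onto ``a`` starting ``offset`` seconds into ``a``.

    The output spans the union of the two supports; ``b`` must overlap ``a``
    at least partially (a non-overlaid scene must be built explicitly).
    """
    if a.rate != b.rate:
        raise ValueError("sample rates differ")
    off_n = int(round(offset * a.rate))
    if off_n >= a.samples.size or off_n + b.samples.size <= 0:
        raise ValueError("offset places the second call entirely outside the first")
    n = max(a.samples.size, off_n + b.samples.size)
    out = np.zeros(n)
    out[: a.samples.size] += a.samples
    start = max(0, off_n)
    out[start : off_n + b.samples.size] += b.samples[start - off_n :]
    return AudioClip(out, a.rate)


def sister_species_variant(spec: CallTypeSpec) -> CallTypeSpec:
    """Trill variant emulating a sister species' contour: two syllables
    separated by a larger gap (detected as separate syllables by a
    long-duration detector)."""
    if spec.name != "trill":
        raise ValueError("the sister-species variant is defined for the trill only")
    return dataclasses.replace(
        spec, n_syllables_range=(2, 2), syllable_gap_range=(0.06, 0.10)
    )


# ---------------------------------------------------------------------------
# scene assembly
# ---------------------------------------------------------------------------

def _white_noise(n: int, rms: float, rng: np.random.Generator) -> np.ndarray:
    return rng.standard_normal(n) * rms


def _noise_burst(rng: np.random.Generator, sample_rate: int) -> Tuple[np.ndarray, float]:
    """Broadband in-band transient (scratching/digging proxy)."""
    dur = rng.uniform(0.03, 0.25)
    amp_rms = rng.uniform(0.12, 0.35)
    n = int(round(dur * sample_rate))
    sos = _signal.butter(4, [BAND_LOW, BAND_HIGH], btype="bandpass", fs=sample_rate, output="sos")
    burst = _signal.sosfiltfilt(sos, rng.standard_normal(n))
    burst *= amp_rms / np.sqrt(np.mean(burst**2))
    burst *= _signal.windows.tukey(n, alpha=0.25)
    return burst, dur


def _render_unit(
    spec: SceneSpec,
    type_spec: CallTypeSpec,
    unit_index: int,
    seed,
) -> Tuple[np.ndarray, List[CallAnnotation]]:
    """One unit (call or series) with the scenario transform applied.

    Returned annotation times are relative to the unit buffer start.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    kid = ss.spawn(2)
    if type_spec.series_size > 1:
        clip, anns = synth_series(type_spec, kid[0], spec.sample_rate, series_id=f"s{unit_index}")
    else:
        clip, ann = synth_call(type_spec, kid[0], spec.sample_rate)
        anns = [ann]

    if spec.scenario == "clipped":
        clip = apply_clipping(clip, spec.clip_level)
    elif spec.scenario == "low_amplitude":
        clip = apply_attenuation(clip, spec.attenuation_db)
    elif spec.scenario == "overlaid":
        partner_type = OVERLAY_PARTNERS[type_spec.name]
        partner_spec = spec.type_spec(partner_type)
        pclip, pann = synth_call(partner_spec, kid[1], spec.sample_rate)
        # superimpose the partner on the (middle) call, starting 40% in
        target = anns[len(anns) // 2]
        offset = target.t_start + 0.4 * target.duration
        clip = overlay_calls(clip, pclip, offset)
        pann = dataclasses.replace(
            pann, t_start=pann.t_start + offset, t_end=pann.t_end + offset
        )
        target.overlaid_with = "partner"  # resolved to real ids by the caller
        pann.overlaid_with = "target"
        anns.append(pann)
    return clip.samples, anns


def _finalize(
    spec: SceneSpec,
    samples: np.ndarray,
    anns: List[CallAnnotation],
) -> Tuple[AudioClip, List[CallAnnotation]]:
    anns = sorted(anns, key=lambda a: (a.t_start, a.t_end))
    pending = [a for a in anns if a.overlaid_with in ("target", "partner")]
    for i, a in enumerate(anns):
        a.id = f"a{i:04d}"
        a.scenario = spec.scenario
    # resolve overlay cross-links between placeholder-marked pairs
    while pending:
        a = pending.pop(0)
        partner = next(
            p for p in pending
            if p.overlaid_with in ("target", "partner")
            and max(a.t_start, p.t_start) < min(a.t_end, p.t_end)
        )
        pending.remove(partner)
        a.overlaid_with, partner.overlaid_with = partner.id, a.id
    return AudioClip(samples, spec.sample_rate), anns


def build_standardized_file(spec: SceneSpec) -> Tuple[AudioClip, List[CallAnnotation]]:
    """One call type per file: ``separator | unit | separator | ... | separator``.

    Separators are ``separator_duration`` seconds of white noise at
    ``separator_noise_db`` dBFS RMS (the noise bed runs under the calls as
    well, as in the source recordings).  For series call types each unit is a
    series of three calls.
    """
    if spec.kind != "standardized":
        raise ValueError("spec.kind must be 'standardized'")
    if len(spec.calls) == 0 or sum(n for _, n in spec.calls) == 0:
        raise ValueError("standardized file needs at least one call")
    if len(spec.calls) != 1:
        raise ValueError("standardized files contain exactly one call type")
    call_type, count = spec.calls[0]
    type_spec = spec.type_spec(call_type)
    n_calls_total = count * type_spec.series_size
    if spec.scenario == "overlaid" and n_calls_total + count < 2:
        raise ValueError("overlaid scenario needs at least two calls")

    ss = np.random.SeedSequence(spec.seed)
    noise_seed, *unit_seeds = ss.spawn(count + 1)
    units = [
        _render_unit(spec, type_spec, i, unit_seeds[i]) for i in range(count)
    ]
    sep_n = int(round(spec.separator_duration * spec.sample_rate))
    total_n = sep_n * (count + 1) + sum(u[0].size for u in units)
    rng = np.random.default_rng(noise_seed)
    samples = _white_noise(total_n, 10 ** (spec.separator_noise_db / 20.0), rng)

    anns: List[CallAnnotation] = []
    cursor = sep_n
    for unit_samples, unit_anns in units:
        samples[cursor : cursor + unit_samples.size] += unit_samples
        t0 = cursor / spec.sample_rate
        for a in unit_anns:
            anns.append(
                dataclasses.replace(a, t_start=a.t_start + t0, t_end=a.t_end + t0)
            )
        cursor += unit_samples.size + sep_n
    return _finalize(spec, samples, anns)


def build_experimental_scene(spec: SceneSpec) -> Tuple[AudioClip, List[CallAnnotation]]:
    """Mixed call types and noise transients at seeded random onsets.

    ``spec.calls`` counts individual calls; series call types are chunked
    into series of up to three.  Units are placed without overlap (scenario
    ``overlaid`` superimposes a partner call inside a unit instead); a
    placement density too high to satisfy after bounded retries is rejected.
    """
    if spec.kind != "experimental":
        raise ValueError("spec.kind must be 'experimental'")
    ss = np.random.SeedSequence(spec.seed)
    bed_seed, place_seed, burst_seed, *unit_seeds = ss.spawn(3 + 4096)
    seed_iter = iter(unit_seeds)

    units: List[Tuple[np.ndarray, List[CallAnnotation]]] = []
    unit_idx = 0
    for call_type, n_calls in spec.calls:
        type_spec = spec.type_spec(call_type)
        remaining = n_calls
        while remaining > 0:
            seed = next(seed_iter)
            take = min(type_spec.series_size, remaining)
            if take > 1:
                clip, anns_u = synth_series(
                    type_spec, seed, spec.sample_rate, series_id=f"s{unit_idx}", n_calls=take
                )
                samples, anns_u = _transform_placed(spec, clip.samples, anns_u, seed)
            else:
                single = (
                    dataclasses.replace(type_spec, series_size=1)
                    if type_spec.series_size > 1
                    else type_spec
                )
                samples, anns_u = _render_unit(spec, single, unit_idx, seed)
            units.append((samples, anns_u))
            remaining -= take
            unit_idx += 1

    rng_burst = np.random.default_rng(burst_seed)
    for _ in range(spec.noise_events):
        burst, dur = _noise_burst(rng_burst, spec.sample_rate)
        ann = CallAnnotation(0.0, dur, BAND_LOW, BAND_HIGH, NOISE_LABEL)
        units.append((burst, [ann]))

    total_content = sum(u[0].size for u in units) / spec.sample_rate
    scene_dur = max(5.0, 2.5 * total_content + len(units) * _PLACEMENT_MARGIN + 2.0)
    n_total = int(round(scene_dur * spec.sample_rate))
    samples = _white_noise(
        n_total, 10 ** (spec.separator_noise_db / 20.0), np.random.default_rng(bed_seed)
    )

    rng_place = np.random.default_rng(place_seed)
    placed: List[Tuple[float, float]] = []
    anns: List[CallAnnotation] = []
    for unit_samples, unit_anns in units:
        dur = unit_samples.size / spec.sample_rate
        onset = None
        for _ in range(2000):
            cand = rng_place.uniform(0.5, scene_dur - dur - 0.5)
            if all(
                cand + dur + _PLACEMENT_MARGIN <= s or cand - _PLACEMENT_MARGIN >= e
                for s, e in placed
            ):
                onset = cand
                break
        if onset is None:
            raise ValueError(
                "could not place all units without overlap; the scene is too dense"
            )
        placed.append((onset, onset + dur))
        i0 = int(round(onset * spec.sample_rate))
        samples[i0 : i0 + unit_samples.size] += unit_samples
        for a in unit_anns:
            anns.append(
                dataclasses.replace(a, t_start=a.t_start + onset, t_end=a.t_end + onset)
            )
    return _finalize(spec, samples, anns)


def _transform_placed(spec: SceneSpec, samples: np.ndarray, anns: List[CallAnnotation], seed):
    """Apply the scenario transform to an already-rendered series unit."""
    clip = AudioClip(samples, spec.sample_rate)
    if spec.scenario == "clipped":
        clip = apply_clipping(clip, spec.clip_level)
    elif spec.scenario == "low_amplitude":
        clip = apply_attenuation(clip, spec.attenuation_db)
    elif spec.scenario == "overlaid":
        type_name = anns[0].call_type
        partner_spec = spec.type_spec(OVERLAY_PARTNERS[type_name])
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        pclip, pann = synth_call(partner_spec, ss.spawn(3)[2], spec.sample_rate)
        target = anns[len(anns) // 2]
        offset = target.t_start + 0.4 * target.duration
        clip = overlay_calls(clip, pclip, offset)
        pann = dataclasses.replace(pann, t_start=pann.t_start + offset, t_end=pann.t_end + offset)
        target.overlaid_with = "partner"
        pann.overlaid_with = "target"
        anns = anns + [pann]
    return clip.samples, anns


__all__ = [
    "CallTypeSpec",
    "SceneSpec",
    "default_call_types",
    "synth_call",
    "synth_series",
    "apply_clipping",
    "apply_attenuation",
    "overlay_calls",
    "sister_species_variant",
    "build_standardized_file",
    "build_experimental_scene",
    "OVERLAY_PARTNERS",
    "SCENARIOS",
    "DEFAULT_SAMPLE_RATE",
    "DEFAULT_SEPARATOR_NOISE_DB",
]
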