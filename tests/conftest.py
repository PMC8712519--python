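import numpy as np
import pytest

from usvpipe.core import AudioClip
from usvpipe.detect import default_profiles
from usvpipe.spectral import compute_spectrogram
from usvpipe.synth import SceneSpec, build_standardized_file, default_call_types

SAMPLE_RATE = 192_000


@pytest.fixture(scope="session")
def call_types():
    return default_call_types()


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


def make_tone(freq: float, duration: float = 0.2, amp: float = 0.7,
              rate: int = SAMPLE_RATE) -> AudioClip:
    t = np.arange(int(duration * rate)) / rate
    return AudioClip(amp * np.sin(2 * np.pi * freq * t), rate)


def make_chirp(f0: float, f1: float, duration: float = 1.0, amp: float = 0.7,
               rate: int = SAMPLE_RATE) -> AudioClip:
    n = int(duration * rate)
    freqs = np.linspace(f0, f1, n)
    phase = 2 * np.pi * np.cumsum(freqs) / rate
    return AudioClip(amp * np.sin(phase), rate)


@pytest.fixture(scope="session")
def good_standardized():
    """Small good-quality standardized file + spectrogram per call type."""
    out = {}
    for ct in ("long_whistle", "trill", "short_whistle", "tsak", "zip"):
        spec = SceneSpec(kind="standardized", calls=((ct, 6),), seed=202)
        clip, anns = build_standardized_file(spec)
        out[ct] = (clip, anns, compute_spectrogram(clip))
    return out
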