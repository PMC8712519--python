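"""File formats: mono PCM WAV, Raven-style selection tables, JSON.

Annotations and detections travel as tab-separated selection tables with
the conventional column names (``Begin Time (s)``, ``End Time (s)``,
``Low Freq (Hz)``, ``High Freq (Hz)``) plus pipeline columns; an
equivalent structured JSON writer is provided for annotations.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .core import AudioClip, CallAnnotation, DetectionBox

_BEGIN, _END = "Begin Time (s)", "End Time (s)"
_LOW, _HIGH = "Low Freq (Hz)", "High Freq (Hz)"


def write_wav(path, clip: AudioClip, dtype: str = "float32") -> None:
    """Write a clip as mono PCM WAV (32-bit float or 16-bit integer)."""
    if dtype == "float32":
        wavfile.write(path, clip.rate, clip.samples.astype(np.float32))
    elif dtype == "int16":
        scaled = np.clip(clip.samples, -1.0, 1.0) * 32767.0
        wavfile.write(path, clip.rate, scaled.astype(np.int16))
    else:
        raise ValueError("dtype must be 'float32' or 'int16'")


def read_wav(path) -> AudioClip:
    """Read a mono PCM WAV; integer formats are rescaled to [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("only mono WAV files are supported")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    return AudioClip(data.astype(np.float64), int(rate))


def annotations_to_frame(annotations: Sequence[CallAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            _BEGIN: [a.t_start for a in annotations],
            _END: [a.t_end for a in annotations],
            _LOW: [a.f_low for a in annotations],
            _HIGH: [a.f_high for a in annotations],
            "call_type": [a.call_type for a in annotations],
            "series_id": [a.series_id for a in annotations],
            "scenario": [a.scenario for a in annotations],
            "overlaid_with": [a.overlaid_with for a in annotations],
            "id": [a.id for a in annotations],
        }
    )


def write_annotations(path, annotations: Sequence[CallAnnotation]) -> None:
    annotations_to_frame(annotations).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> List[CallAnnotation]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(
            CallAnnotation(
                t_start=float(row[_BEGIN]),
                t_end=float(row[_END]),
                f_low=float(row[_LOW]),
                f_high=float(row[_HIGH]),
                call_type=str(row["call_type"]),
                series_id=_opt(row.get("series_id")),
                scenario=str(row.get("scenario", "good")),
                overlaid_with=_opt(row.get("overlaid_with")),
                id=_opt(row.get("id")),
            )
        )
    return out


def write_annotations_json(path, annotations: Sequence[CallAnnotation]) -> None:
    records = annotations_to_frame(annotations).to_dict(orient="records")
    Path(path).write_text(json.dumps(records, indent=1))


def detections_to_frame(boxes: Sequence[DetectionBox]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            _BEGIN: [b.t_start for b in boxes],
            _END: [b.t_end for b in boxes],
            _LOW: [b.f_low for b in boxes],
            _HIGH: [b.f_high for b in boxes],
            "score": [b.score for b in boxes],
            "source_detector": [b.source_detector for b in boxes],
            "label": [b.label for b in boxes],
            "status": [b.status for b in boxes],
        }
    )


def write_detections(path, boxes: Sequence[DetectionBox]) -> None:
    detections_to_frame(boxes).to_csv(path, sep="\t", index=False)


def read_detections(path) -> List[DetectionBox]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(
            DetectionBox(
                t_start=float(row[_BEGIN]),
                t_end=float(row[_END]),
                f_low=float(row[_LOW]),
                f_high=float(row[_HIGH]),
                score=float(row["score"]),
                source_detector=str(row["source_detector"]),
                label=_opt(row.get("label")),
                status=str(row.get("status", "raw")),
            )
        )
    return out


def _opt(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return str(value)


__all__ = [
    "write_wav",
    "read_wav",
    "annotations_to_frame",
    "write_annotations",
    "read_annotations",
    "write_annotations_json",
    "detections_to_frame",
    "write_detections",
    "read_detections",
]
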