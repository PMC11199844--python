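"""WAV audio and bounding-box annotation I/O.

This is the format boundary of the pipeline.  Audio is mono 16-bit PCM WAV
(the format written by collar-mounted recorders); annotations are
time-frequency bounding boxes with a binary presence/absence label, stored
as plain CSV.  An import shim accepts Sonic Visualiser "boxes layer" CSV
exports and converts them to the canonical dialect.

Time convention: seconds from file start, half-open intervals ``[start, end)``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "AudioClip",
    "AnnotationBox",
    "read_wav",
    "write_wav",
    "read_boxes",
    "write_boxes",
    "read_sonic_visualiser_boxes",
    "UnsupportedFormatError",
    "AnnotationValidationError",
]

BOX_COLUMNS = ["file", "start_s", "end_s", "fmin_hz", "fmax_hz", "label"]
LABELS = ("presence", "absence")


class UnsupportedFormatError(ValueError):
    """Raised for audio files that are not mono 16-bit PCM WAV."""


class AnnotationValidationError(ValueError):
    """Raised when annotation rows violate box invariants; lists row numbers."""


@dataclass
class AudioClip:
    """A mono audio signal: float samples in [-1, 1] plus a sample rate."""

    samples: np.ndarray
    sample_rate_hz: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise UnsupportedFormatError(
                f"expected mono audio, got {self.samples.ndim}-dimensional samples"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio samples must be finite")
        if not (isinstance(self.sample_rate_hz, (int, np.integer)) and self.sample_rate_hz > 0):
            raise ValueError(f"sample_rate_hz must be a positive integer, got {self.sample_rate_hz}")
        self.sample_rate_hz = int(self.sample_rate_hz)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    @property
    def nyquist_hz(self) -> float:
        return self.sample_rate_hz / 2.0

    def slice_seconds(self, start_s: float, end_s: float) -> "AudioClip":
        """Return the samples in [start_s, end_s) as a new clip."""
        i0 = int(round(start_s * self.sample_rate_hz))
        i1 = int(round(end_s * self.sample_rate_hz))
        i0 = max(i0, 0)
        return AudioClip(self.samples[i0:i1].copy(), self.sample_rate_hz)


@dataclass(frozen=True)
class AnnotationBox:
    """A labelled time-frequency box; ground truth for training and scoring."""

    file_id: str
    start_s: float
    end_s: float
    fmin_hz: float
    fmax_hz: float
    label: str

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ValueError(
                f"box times must satisfy 0 <= start < end, got [{self.start_s}, {self.end_s})"
            )
        if not (0 <= self.fmin_hz < self.fmax_hz):
            raise ValueError(
                f"box frequencies must satisfy 0 <= fmin < fmax, got [{self.fmin_hz}, {self.fmax_hz}]"
            )
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def read_wav(path) -> AudioClip:
    """Read a mono 16-bit PCM WAV file into an :class:`AudioClip`.

    Integer samples are scaled by 1/32768 so that a write/read roundtrip of
    16-bit data is sample-exact.  Non-PCM or multichannel input is rejected.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise UnsupportedFormatError(f"cannot read {path}: {exc}") from exc
    if data.ndim != 1:
        raise UnsupportedFormatError(
            f"{path}: expected mono audio, got {data.shape[1]} channels"
        )
    if data.dtype != np.int16:
        raise UnsupportedFormatError(
            f"{path}: expected 16-bit PCM samples, got dtype {data.dtype}"
        )
    return AudioClip(data.astype(np.float64) / 32768.0, int(rate))


def write_wav(path, clip: AudioClip):
    """Write a clip as mono 16-bit PCM WAV; returns the path written."""
    path = Path(path)
    scaled = np.clip(np.round(clip.samples * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, clip.sample_rate_hz, scaled)
    return path


def _validate_box_frame(df: pd.DataFrame, source: str) -> list[AnnotationBox]:
    missing = [c for c in BOX_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationValidationError(f"{source}: missing columns {missing}")
    boxes: list[AnnotationBox] = []
    bad_rows: list[str] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        try:
            boxes.append(
                AnnotationBox(
                    file_id=str(row.file),
                    start_s=float(row.start_s),
                    end_s=float(row.end_s),
                    fmin_hz=float(row.fmin_hz),
                    fmax_hz=float(row.fmax_hz),
                    label=str(row.label),
                )
            )
        except (ValueError, TypeError) as exc:
            bad_rows.append(f"row {row_no}: {exc}")
    if bad_rows:
        raise AnnotationValidationError(
            f"{source}: {len(bad_rows)} invalid annotation row(s):\n" + "\n".join(bad_rows)
        )
    return boxes


def read_boxes(path) -> list[AnnotationBox]:
    """Read an annotation CSV; rows violating box invariants are rejected
    with their row numbers."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        return []
    return _validate_box_frame(df, str(path))


def write_boxes(path, boxes) -> Path:
    """Write boxes to the canonical CSV dialect (times/frequencies to 6 dp)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "file": [b.file_id for b in boxes],
            "start_s": [round(b.start_s, 6) for b in boxes],
            "end_s": [round(b.end_s, 6) for b in boxes],
            "fmin_hz": [round(b.fmin_hz, 6) for b in boxes],
            "fmax_hz": [round(b.fmax_hz, 6) for b in boxes],
            "label": [b.label for b in boxes],
        },
        columns=BOX_COLUMNS,
    )
    df.to_csv(path, index=False)
    return path


def read_sonic_visualiser_boxes(path, file_id: str, label: str = "presence") -> list[AnnotationBox]:
    """Import a Sonic Visualiser boxes-layer CSV export.

    SV box layers export rows of ``time, value, duration, extent, label``
    (seconds, Hz); ``value`` is the lower frequency edge and ``extent`` the
    frequency span.  The SV label column, when present and matching one of
    the canonical labels, overrides `label`.
    """
    path = Path(path)
    df = pd.read_csv(path, header=None)
    if df.shape[1] < 4:
        raise AnnotationValidationError(
            f"{path}: expected >=4 columns (time, value, duration, extent)"
        )
    boxes = []
    for _, row in df.iterrows():
        row_label = label
        if df.shape[1] >= 5 and str(row[4]).strip() in LABELS:
            row_label = str(row[4]).strip()
        start = float(row[0])
        fmin = float(row[1])
        boxes.append(
            AnnotationBox(
                file_id=file_id,
                start_s=start,
                end_s=start + float(row[2]),
                fmin_hz=fmin,
                fmax_hz=fmin + float(row[3]),
                label=row_label,
            )
        )
    return boxes
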