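"""Segment-based scoring of detections against ground-truth boxes.

Time is discretized into fixed 1-s frames (the detector's inference hop).
A frame is truth-positive when it overlaps any presence box and
predicted-positive when it overlaps any detection event; recall,
precision, accuracy and F1 are computed from the pooled confusion counts.
Undefined ratios (zero denominators) are reported as NaN with an explicit
flag, never silently as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .audio_io import AnnotationBox, read_boxes, read_wav
from .detector import DetectionEvent

__all__ = ["ConfusionCounts", "frame_confusion", "metrics", "evaluate_files", "read_events_csv", "write_events_csv"]

METRIC_NAMES = ("recall", "precision", "accuracy", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


def _mark(intervals, n_frames: int, frame_s: float) -> np.ndarray:
    """Boolean frame track: frame f is True iff any interval overlaps
    [f*frame_s, (f+1)*frame_s)."""
    track = np.zeros(n_frames, dtype=bool)
    for start, end in intervals:
        f0 = max(0, int(np.floor(start / frame_s + 1e-9)))
        f1 = min(n_frames, int(np.ceil(end / frame_s - 1e-9)))
        track[f0:f1] = True
    return track


def frame_confusion(
    truth_boxes: list[AnnotationBox],
    events: list[DetectionEvent],
    file_duration_s: float,
    frame_s: float = 1.0,
) -> ConfusionCounts:
    """Tally frame-level confusion counts for one file."""
    if file_duration_s < 0:
        raise ValueError("file duration must be non-negative")
    n_frames = int(np.ceil(file_duration_s / frame_s - 1e-9))
    truth = _mark(
        [(b.start_s, b.end_s) for b in truth_boxes if b.label == "presence"], n_frames, frame_s
    )
    pred = _mark([(e.start_s, e.end_s) for e in events], n_frames, frame_s)
    return ConfusionCounts(
        tp=int(np.sum(truth & pred)),
        fp=int(np.sum(~truth & pred)),
        tn=int(np.sum(~truth & ~pred)),
        fn=int(np.sum(truth & ~pred)),
    )


def metrics(counts: ConfusionCounts) -> dict:
    """Recall, precision, accuracy and F1 from confusion counts.

    Returns NaN plus an entry in ``undefined`` for any ratio whose
    denominator is zero.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero frames")
    out: dict = {"undefined": []}

    def ratio(name, num, den):
        if den == 0:
            out[name] = float("nan")
            out["undefined"].append(name)
        else:
            out[name] = num / den

    ratio("recall", counts.tp, counts.tp + counts.fn)
    ratio("precision", counts.tp, counts.tp + counts.fp)
    ratio("accuracy", counts.tp + counts.tn, counts.total)
    p, r = out["precision"], out["recall"]
    if np.isnan(p) or np.isnan(r) or (p + r) == 0:
        out["f1"] = float("nan")
        out["undefined"].append("f1")
    else:
        out["f1"] = 2 * p * r / (p + r)
    return out


def write_events_csv(path, events: list[DetectionEvent], file_id: str) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "file": [file_id] * len(events),
            "start_s": [e.start_s for e in events],
            "end_s": [e.end_s for e in events],
            "mean_score": [e.mean_score for e in events],
        },
        columns=["file", "start_s", "end_s", "mean_score"],
    ).to_csv(path, index=False)
    return path


def read_events_csv(path) -> list[DetectionEvent]:
    df = pd.read_csv(path)
    return [
        DetectionEvent(start_s=float(r.start_s), end_s=float(r.end_s), mean_score=float(r.mean_score))
        for r in df.itertuples(index=False)
    ]


def evaluate_files(truth_dir, events_dir, frame_s: float = 1.0) -> pd.DataFrame:
    """Score every file in `truth_dir` against its events CSV.

    `truth_dir` holds `<file_id>.wav` + `<file_id>.csv` (annotation boxes);
    `events_dir` holds `<file_id>.csv` (events).  Returns one row per file
    plus a micro-averaged ``pooled`` row (metrics of the summed counts) and
    a ``macro`` row (mean of per-file metrics).  Unmatched files raise.
    """
    truth_dir, events_dir = Path(truth_dir), Path(events_dir)
    truth_ids = {p.stem for p in truth_dir.glob("*.wav")}
    event_ids = {p.stem for p in events_dir.glob("*.csv")}
    if not truth_ids:
        raise ValueError(f"no WAV files found in {truth_dir}")
    unmatched = sorted(truth_ids ^ event_ids)
    if unmatched:
        raise ValueError(
            f"unmatched files between {truth_dir} and {events_dir}: {unmatched}"
        )
    rows = []
    pooled = ConfusionCounts()
    per_file_metrics = []
    for fid in sorted(truth_ids):
        clip = read_wav(truth_dir / f"{fid}.wav")
        boxes = read_boxes(truth_dir / f"{fid}.csv")
        events = read_events_csv(events_dir / f"{fid}.csv")
        counts = frame_confusion(boxes, events, clip.duration_s, frame_s)
        m = metrics(counts)
        per_file_metrics.append(m)
        pooled = pooled + counts
        rows.append(
            dict(file=fid, tp=counts.tp, fp=counts.fp, tn=counts.tn, fn=counts.fn,
                 **{k: m[k] for k in METRIC_NAMES})
        )
    mp = metrics(pooled)
    rows.append(
        dict(file="pooled", tp=pooled.tp, fp=pooled.fp, tn=pooled.tn, fn=pooled.fn,
             **{k: mp[k] for k in METRIC_NAMES})
    )
    rows.append(
        dict(file="macro", tp=pooled.tp, fp=pooled.fp, tn=pooled.tn, fn=pooled.fn,
             **{k: float(np.nanmean([m[k] for m in per_file_metrics])) for k in METRIC_NAMES})
    )
    return pd.DataFrame(rows)
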