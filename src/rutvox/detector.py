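"""Grunt detector: CNN training and whole-file sliding-window inference.

Inference classifies 4-s windows at a 1-s hop with two softmax outputs; a
window is positive when its presence probability exceeds 0.5.  Positive
windows are projected onto 1-s frames (a frame is positive when any
covering window is positive) and maximal positive runs become detection
events.
"""

from __future__ import annotations

import hashlib
import json
import tempfile
import zipfile
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .audio_io import AudioClip
from .nnet import AdamState, CompactCNN
from .preprocessing import (
    PreprocConfig,
    SpectrogramTensor,
    _slice_padded,
    _tensor_from_audio,
    preprocess_clip,
)

__all__ = [
    "TrainConfig",
    "WindowPrediction",
    "DetectionEvent",
    "build_model",
    "train",
    "predict_file",
    "windows_to_frames",
    "frames_to_events",
    "save_checkpoint",
    "load_checkpoint",
    "dataset_to_arrays",
    "manifest_hash",
]

LABEL_TO_CLASS = {"absence": 0, "presence": 1}


@dataclass(frozen=True)
class TrainConfig:
    """Detector training hyper-parameters."""

    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    backbone: str = "compact"
    channels: tuple = (8, 16, 32)
    fine_tune_feature_extractor: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class WindowPrediction:
    """Softmax output for one 4-s analysis window."""

    window_start_s: float
    p_presence: float
    p_absence: float

    def __post_init__(self) -> None:
        if not (self.p_presence >= 0 and self.p_absence >= 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.p_presence + self.p_absence - 1.0) > 1e-5:
            raise ValueError("softmax probabilities must sum to 1")


@dataclass(frozen=True)
class DetectionEvent:
    """A merged positive interval with its mean window score."""

    start_s: float
    end_s: float
    mean_score: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("event end must exceed its start")


def build_model(config: TrainConfig, input_shape=(128, 126, 3)) -> CompactCNN:
    """Construct the two-class CNN for `input_shape` spectrogram tensors.

    Only the compact backbone is available; a pretrained image backbone
    would need a deep-learning framework and is rejected explicitly.
    """
    if config.backbone != "compact":
        raise NotImplementedError(
            f"backbone {config.backbone!r} is not available; this build provides "
            "the compact CNN backbone only"
        )
    return CompactCNN(input_shape, channels=config.channels, seed=config.seed)


def dataset_to_arrays(segments: list[SpectrogramTensor]) -> tuple[np.ndarray, np.ndarray]:
    """Stack labelled tensors into (X, y) training arrays."""
    X = np.stack([s.values for s in segments]).astype(np.float32)
    y = np.array([LABEL_TO_CLASS[s.label] for s in segments], dtype=np.int64)
    return X, y


def train(
    model: CompactCNN,
    dataset: list[SpectrogramTensor] | tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
) -> dict:
    """Train in place; returns a history dict with per-epoch loss/accuracy."""
    if isinstance(dataset, tuple):
        X, y = dataset
    else:
        if not dataset:
            raise ValueError("training dataset is empty")
        X, y = dataset_to_arrays(dataset)
    if len(X) == 0:
        raise ValueError("training dataset is empty")
    rng = np.random.default_rng(config.seed)
    adam = AdamState(lr=config.learning_rate)
    history = {"loss": [], "accuracy": []}
    for _epoch in range(config.epochs):
        order = rng.permutation(len(X))
        losses, accs = [], []
        for i in range(0, len(X), config.batch_size):
            idx = order[i : i + config.batch_size]
            loss, acc = model.train_step(X[idx], y[idx], adam)
            losses.append(loss)
            accs.append(acc)
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(float(np.mean(accs)))
    return history


def _window_start_times(duration_s: float, segment_s: float, hop_s: float) -> list[float]:
    """Start times 0, hop, 2*hop, ... covering the whole recording; a final
    partial window (zero-padded) is included when the duration is not an
    exact multiple of the hop."""
    last = max(0.0, np.ceil((duration_s - segment_s) / hop_s - 1e-9) * hop_s)
    n = int(round(last / hop_s)) + 1
    return [k * hop_s for k in range(n)]


def predict_file(
    model: CompactCNN,
    clip: AudioClip,
    config: PreprocConfig | None = None,
    batch_size: int = 64,
) -> list[WindowPrediction]:
    """Sliding-window prediction over a whole recording.

    4-s windows shift 1 s at a time until the entire recording is
    processed; trailing audio shorter than one window is zero-padded.
    Raw input is preprocessed (low-pass + downsample) internally.
    """
    config = config or PreprocConfig()
    proc = preprocess_clip(clip, config)
    starts = _window_start_times(clip.duration_s, config.segment_s, config.train_stride_s)
    tensors = []
    for s in starts:
        samples = _slice_padded(proc.samples, proc.sample_rate_hz, s, config.segment_samples)
        tensors.append(_tensor_from_audio(samples, config, "none", "", s))
    X = np.stack([t.values for t in tensors]).astype(np.float32)
    probs = model.predict_proba(X, batch_size=batch_size)
    return [
        WindowPrediction(window_start_s=float(s), p_presence=float(p[1]), p_absence=float(p[0]))
        for s, p in zip(starts, probs)
    ]


def windows_to_frames(
    predictions: list[WindowPrediction],
    file_duration_s: float,
    threshold: float = 0.5,
    segment_s: float = 4.0,
    rule: str = "any",
    frame_s: float = 1.0,
) -> np.ndarray:
    """Project window predictions onto a per-second binary track.

    With ``rule="any"`` a frame is positive iff at least one covering
    window is above threshold (the recall-maximizing detection semantic);
    ``rule="majority"`` requires more than half of the covering windows.
    """
    if rule not in ("any", "majority"):
        raise ValueError(f"unknown rule {rule!r}")
    n_frames = int(np.ceil(file_duration_s / frame_s - 1e-9))
    pos = np.zeros(n_frames, dtype=int)
    cover = np.zeros(n_frames, dtype=int)
    for p in predictions:
        f0 = int(np.floor(p.window_start_s / frame_s + 1e-9))
        f1 = min(n_frames, int(np.ceil((p.window_start_s + segment_s) / frame_s - 1e-9)))
        cover[f0:f1] += 1
        if p.p_presence > threshold:
            pos[f0:f1] += 1
    if rule == "any":
        return pos > 0
    return pos * 2 > cover


def frames_to_events(
    track: np.ndarray,
    predictions: list[WindowPrediction] | None = None,
    frame_s: float = 1.0,
    segment_s: float = 4.0,
) -> list[DetectionEvent]:
    """Merge maximal runs of positive frames into detection events.

    When window predictions are supplied, each event's score is the mean
    presence probability of the windows overlapping it; otherwise 1.0.
    """
    track = np.asarray(track, dtype=bool)
    events: list[DetectionEvent] = []
    n = track.size
    i = 0
    while i < n:
        if not track[i]:
            i += 1
            continue
        j = i
        while j < n and track[j]:
            j += 1
        start, end = i * frame_s, j * frame_s
        score = 1.0
        if predictions:
            scores = [
                p.p_presence
                for p in predictions
                if p.window_start_s < end and p.window_start_s + segment_s > start
            ]
            if scores:
                score = float(np.mean(scores))
        events.append(DetectionEvent(start_s=start, end_s=end, mean_score=score))
        i = j
    return events


# --- checkpointing -------------------------------------------------------


def manifest_hash(segments: list[SpectrogramTensor]) -> str:
    """Hash of the dataset manifest (provenance + labels), for audit."""
    h = hashlib.sha256()
    for s in segments:
        h.update(f"{s.source[0]}:{s.source[1]:.6f}:{s.label};".encode())
    return h.hexdigest()


def save_checkpoint(path, model: CompactCNN, config: TrainConfig, manifest: str = "") -> Path:
    """Single-file archive: weights (npz) + train config + manifest hash."""
    path = Path(path)
    meta = {
        "config": asdict(config),
        "input_shape": list(model.input_shape),
        "manifest_hash": manifest,
    }
    with zipfile.ZipFile(path, "w") as zf:
        with tempfile.NamedTemporaryFile(suffix=".npz") as tmp:
            np.savez(tmp.name, **model.named_parameters())
            zf.write(tmp.name, "weights.npz")
        zf.writestr("meta.json", json.dumps(meta, indent=2))
    return path


def load_checkpoint(path) -> tuple[CompactCNN, TrainConfig, str]:
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        with tempfile.TemporaryDirectory() as tmpdir:
            zf.extract("weights.npz", tmpdir)
            weights = dict(np.load(Path(tmpdir) / "weights.npz"))
    cfg_dict = meta["config"]
    cfg_dict["channels"] = tuple(cfg_dict["channels"])
    config = TrainConfig(**cfg_dict)
    model = build_model(config, input_shape=tuple(meta["input_shape"]))
    model.set_parameters(weights)
    return model, config, meta["manifest_hash"]
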