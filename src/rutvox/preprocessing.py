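"""Audio-to-tensor preprocessing for the grunt detector.

The chain is: zero-phase low-pass at 1 kHz -> downsample to 8 kHz
(Nyquist 4 kHz) -> 4-s windows anchored at annotation-box start times ->
128-bin mel spectrogram (Hann 1024, hop 256, 0-4000 Hz) -> log-power,
per-segment min-max normalization to [0, 1] -> elementwise exponent
channels S^1, S^3, S^5.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .audio_io import AnnotationBox, AudioClip

__all__ = [
    "PreprocConfig",
    "SpectrogramTensor",
    "low_pass",
    "resample",
    "window_starts",
    "segments_from_annotations",
    "augment_time_shift",
    "balance_classes",
    "mel_spectrogram",
    "expand_channels",
    "mel_filterbank",
    "preprocess_clip",
]


@dataclass(frozen=True)
class PreprocConfig:
    """Preprocessing hyper-parameters (defaults are the tuned values)."""

    lowpass_hz: float = 1000.0
    target_rate_hz: int = 8000
    segment_s: float = 4.0
    hann_samples: int = 1024
    hop_samples: int = 256
    n_mel: int = 128
    fmin_hz: float = 0.0
    fmax_hz: float = 4000.0
    train_stride_s: float = 1.0
    exponents: tuple = (1, 3, 5)

    def __post_init__(self) -> None:
        if self.fmax_hz > self.nyquist_hz:
            raise ValueError(
                f"fmax {self.fmax_hz} exceeds the Nyquist rate {self.nyquist_hz}"
            )
        if self.hop_samples > self.hann_samples:
            raise ValueError("hop must not exceed the Hann window length")
        if abs(self.segment_s * self.target_rate_hz - round(self.segment_s * self.target_rate_hz)) > 1e-9:
            raise ValueError("segment_s x target_rate_hz must be an integer sample count")

    @property
    def nyquist_hz(self) -> float:
        return self.target_rate_hz / 2.0

    @property
    def segment_samples(self) -> int:
        return int(round(self.segment_s * self.target_rate_hz))

    @property
    def n_frames(self) -> int:
        # centered framing: one frame per hop plus the frame at the end
        return self.segment_samples // self.hop_samples + 1


@dataclass
class SpectrogramTensor:
    """A labelled mel x frame x channel array in [0, 1] with provenance."""

    values: np.ndarray  # (n_mel, n_frames, n_channels)
    label: str  # presence | absence | none
    source: tuple  # (file_id, window_start_s)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("tensor values must be 3-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tensor values must be finite")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("tensor values must lie in [0, 1]")
        if self.label not in ("presence", "absence", "none"):
            raise ValueError(f"unknown label {self.label!r}")


def low_pass(clip: AudioClip, cutoff_hz: float) -> AudioClip:
    """Zero-phase 8th-order Butterworth low-pass (applied forward-backward),
    the anti-aliasing step before downsampling."""
    nyq = clip.sample_rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency {nyq} Hz")
    if clip.samples.size == 0:
        return AudioClip(clip.samples.copy(), clip.sample_rate_hz)
    sos = sps.butter(8, cutoff_hz, btype="low", fs=clip.sample_rate_hz, output="sos")
    return AudioClip(sps.sosfiltfilt(sos, clip.samples), clip.sample_rate_hz)


def lowpass_response_db(cutoff_hz: float, freq_hz: float, sample_rate_hz: int) -> float:
    """Magnitude response (dB) of the zero-phase low-pass at `freq_hz`.

    The forward-backward pass squares the Butterworth magnitude response.
    """
    sos = sps.butter(8, cutoff_hz, btype="low", fs=sample_rate_hz, output="sos")
    _w, h = sps.sosfreqz(sos, worN=[freq_hz], fs=sample_rate_hz)
    return float(40.0 * np.log10(np.abs(h[0]) + 1e-300))  # 2x20: two passes


def resample(clip: AudioClip, target_rate_hz: int) -> AudioClip:
    """Polyphase downsampling to `target_rate_hz` (upsampling is out of scope)."""
    if target_rate_hz > clip.sample_rate_hz:
        raise ValueError(
            f"upsampling ({clip.sample_rate_hz} -> {target_rate_hz} Hz) is not supported"
        )
    if target_rate_hz == clip.sample_rate_hz:
        return AudioClip(clip.samples.copy(), clip.sample_rate_hz)
    frac = Fraction(int(target_rate_hz), int(clip.sample_rate_hz))
    out = sps.resample_poly(clip.samples, frac.numerator, frac.denominator)
    return AudioClip(out, int(target_rate_hz))


def preprocess_clip(clip: AudioClip, config: PreprocConfig) -> AudioClip:
    """Low-pass then downsample, unless the clip is already at the target rate."""
    if clip.sample_rate_hz == config.target_rate_hz:
        return clip
    return resample(low_pass(clip, config.lowpass_hz), config.target_rate_hz)


def window_starts(box: AnnotationBox, segment_s: float, stride_s: float) -> list[float]:
    """Window start times for one annotation box.

    Windows begin at the box start and advance by `stride_s` while they
    still fit inside the box; a box shorter than one window yields the
    single start at the box start.
    """
    if stride_s <= 0:
        raise ValueError("stride must be positive")
    dur = box.end_s - box.start_s
    if dur < segment_s:
        return [box.start_s]
    n = int(np.floor((dur - segment_s) / stride_s + 1e-9)) + 1
    return [box.start_s + k * stride_s for k in range(n)]


def _slice_padded(samples: np.ndarray, rate: int, start_s: float, length: int) -> np.ndarray:
    """Slice `length` samples at `start_s`, zero-padding past end-of-file."""
    i0 = int(round(start_s * rate))
    seg = samples[i0 : i0 + length]
    if seg.size < length:
        seg = np.concatenate([seg, np.zeros(length - seg.size)])
    return seg


def mel_filterbank(n_mel: int, n_fft: int, rate: int, fmin: float, fmax: float) -> np.ndarray:
    """Triangular mel filterbank (HTK mel scale), shape (n_mel, n_fft//2+1)."""

    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)

    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mel + 2)
    hz_pts = mel_to_hz(mel_pts)
    fft_freqs = np.linspace(0, rate / 2, n_fft // 2 + 1)
    fb = np.zeros((n_mel, fft_freqs.size))
    for m in range(n_mel):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def _stft_power(x: np.ndarray, n_fft: int, hop: int) -> np.ndarray:
    """Power spectrogram with centered framing: floor(N/hop)+1 frames."""
    n = x.size
    pad = n_fft // 2
    xp = np.pad(x, pad, mode="reflect")
    n_frames = n // hop + 1
    idx = np.arange(n_fft)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = xp[idx] * np.hanning(n_fft)[None, :]
    spec = np.fft.rfft(frames, axis=1)
    return (np.abs(spec) ** 2).T  # (n_fft//2+1, n_frames)


def mel_spectrogram(segment: AudioClip, config: PreprocConfig) -> np.ndarray:
    """Single-channel normalized mel spectrogram of one exact-length segment.

    Log-power (dB) scaling followed by per-segment min-max normalization to
    [0, 1]; a constant segment (e.g. digital silence) maps to all zeros.
    """
    if segment.sample_rate_hz != config.target_rate_hz:
        raise ValueError(
            f"segment rate {segment.sample_rate_hz} != target {config.target_rate_hz}; "
            "preprocess first"
        )
    if segment.samples.size != config.segment_samples:
        raise ValueError(
            f"segment has {segment.samples.size} samples, expected {config.segment_samples}"
        )
    power = _stft_power(segment.samples, config.hann_samples, config.hop_samples)
    fb = mel_filterbank(
        config.n_mel, config.hann_samples, config.target_rate_hz, config.fmin_hz, config.fmax_hz
    )
    mel = fb @ power
    log_mel = 10.0 * np.log10(mel + 1e-10)
    lo, hi = log_mel.min(), log_mel.max()
    if hi - lo < 1e-12:
        return np.zeros_like(log_mel)
    return (log_mel - lo) / (hi - lo)


def expand_channels(spectrogram: np.ndarray, exponents: tuple = (1, 3, 5)) -> np.ndarray:
    """Stack elementwise powers of a [0,1] spectrogram as channels.

    Raising a contrast-normalized spectrogram to increasing odd powers
    progressively suppresses faint background structure, giving the CNN
    three views of the same segment at different contrast.
    """
    spectrogram = np.asarray(spectrogram)
    if spectrogram.min() < 0 or spectrogram.max() > 1:
        raise ValueError("expand_channels requires values in [0, 1]")
    return np.stack([spectrogram**e for e in exponents], axis=-1)


def _tensor_from_audio(
    samples: np.ndarray, config: PreprocConfig, label: str, file_id: str, start_s: float
) -> SpectrogramTensor:
    seg = AudioClip(samples, config.target_rate_hz)
    spec = mel_spectrogram(seg, config)
    return SpectrogramTensor(
        values=expand_channels(spec, config.exponents).astype(np.float32),
        label=label,
        source=(file_id, float(start_s)),
    )


def segments_from_annotations(
    clip: AudioClip,
    boxes: list[AnnotationBox],
    config: PreprocConfig,
    file_id: str | None = None,
) -> list[SpectrogramTensor]:
    """Labelled spectrogram tensors for every (box, window-start) pair.

    The clip may be raw (low-pass + downsample are applied) or already at
    the target rate.  Windows that run past end-of-file are zero-padded to
    the full segment length.
    """
    proc = preprocess_clip(clip, config)
    rate = proc.sample_rate_hz
    out: list[SpectrogramTensor] = []
    for box in boxes:
        if box.start_s >= clip.duration_s:
            raise ValueError(
                f"box [{box.start_s}, {box.end_s}) of {box.file_id!r} starts beyond "
                f"end of file ({clip.duration_s:.2f}s)"
            )
        fid = file_id if file_id is not None else box.file_id
        for start in window_starts(box, config.segment_s, config.train_stride_s):
            samples = _slice_padded(proc.samples, rate, start, config.segment_samples)
            out.append(_tensor_from_audio(samples, config, box.label, fid, start))
    return out


def augment_time_shift(
    segments: list[SpectrogramTensor],
    target_count: int,
    seed: int,
    audio_by_file: dict,
    config: PreprocConfig,
) -> list[SpectrogramTensor]:
    """Grow `segments` to `target_count` by time-shifting existing ones.

    Each added copy re-slices the source audio at a uniform shift of
    magnitude < segment_s/2 from an existing window start (clamped to the
    file start), so augmented tensors are genuine audio windows rather
    than rolled arrays.  `audio_by_file` maps file_id to the (raw or
    preprocessed) source clip.
    """
    if target_count < 0:
        raise ValueError("target_count must be >= 0")
    if len(segments) >= target_count or not segments:
        return list(segments)
    rng = np.random.default_rng(seed)
    proc_cache = {fid: preprocess_clip(c, config) for fid, c in audio_by_file.items()}
    out = list(segments)
    half = config.segment_s / 2.0
    while len(out) < target_count:
        base = segments[int(rng.integers(0, len(segments)))]
        fid, start = base.source
        shift = rng.uniform(-half, half)
        new_start = max(0.0, start + shift)
        proc = proc_cache[fid]
        samples = _slice_padded(
            proc.samples, proc.sample_rate_hz, new_start, config.segment_samples
        )
        out.append(_tensor_from_audio(samples, config, base.label, fid, new_start))
    return out


def balance_classes(
    presence: list[SpectrogramTensor],
    absence: list[SpectrogramTensor],
    seed: int,
) -> tuple[list[SpectrogramTensor], list[SpectrogramTensor]]:
    """Randomly subsample the majority class (without replacement) to the
    minority class size."""
    if not presence or not absence:
        raise ValueError("both classes must be non-empty")
    rng = np.random.default_rng(seed)
    n = min(len(presence), len(absence))

    def sub(lst):
        if len(lst) == n:
            return list(lst)
        keep = rng.choice(len(lst), size=n, replace=False)
        return [lst[i] for i in np.sort(keep)]

    return sub(presence), sub(absence)
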