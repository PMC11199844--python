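"""End-to-end orchestration: synth -> preprocess -> train -> detect ->
evaluate -> behavioural analysis, with a reproducibility manifest.

Every stage writes under one output directory; the manifest records stage
configs, seeds and SHA-256 hashes of every artifact so a rerun with the
same config can be audited byte-for-byte for the deterministic stages.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .audio_io import read_boxes, read_wav
from .behaviour import fit_hgam, predict_smooths, status_contrast_test, diagnostics
from .detector import (
    TrainConfig,
    build_model,
    frames_to_events,
    manifest_hash,
    predict_file,
    save_checkpoint,
    train,
    windows_to_frames,
)
from .evaluation import evaluate_files, write_events_csv
from .hgam import HGAMSpec
from .preprocessing import PreprocConfig, balance_classes, segments_from_annotations
from .synth import BehaviourParams, synth_behaviour_series, synth_benchmark

__all__ = ["run_all", "default_config", "build_training_set", "train_on_benchmark", "detect_directory"]


def default_config(seed: int = 0) -> dict:
    return {
        "seed": seed,
        "benchmark": {"n_train_scenes": 10, "n_test_scenes": 4, "difficulty": "default"},
        "preprocessing": {},
        "training": {"epochs": 10, "batch_size": 32, "learning_rate": 1e-3},
        "detection": {"threshold": 0.5},
        "behaviour": {"n_individuals": 8, "status_effect": 1.5, "n_records": 2000},
    }


def build_training_set(data_dir, preproc: PreprocConfig, seed: int):
    """Balanced labelled tensors from a benchmark train split."""
    data_dir = Path(data_dir)
    presence, absence = [], []
    for wav in sorted(data_dir.glob("*.wav")):
        clip = read_wav(wav)
        boxes = read_boxes(wav.with_suffix(".csv"))
        for seg in segments_from_annotations(clip, boxes, preproc, file_id=wav.stem):
            (presence if seg.label == "presence" else absence).append(seg)
    presence, absence = balance_classes(presence, absence, seed=seed)
    return presence + absence


def train_on_benchmark(bench_dir, train_config: TrainConfig, preproc: PreprocConfig | None = None):
    """Train the compact CNN on a benchmark's train split."""
    preproc = preproc or PreprocConfig()
    dataset = build_training_set(Path(bench_dir) / "train", preproc, seed=train_config.seed)
    model = build_model(train_config, input_shape=dataset[0].values.shape)
    history = train(model, dataset, train_config)
    return model, history, manifest_hash(dataset)


def detect_directory(model, wav_dir, out_dir, preproc: PreprocConfig | None = None, threshold: float = 0.5):
    """Run sliding-window detection on every WAV in `wav_dir`; write event CSVs."""
    preproc = preproc or PreprocConfig()
    wav_dir, out_dir = Path(wav_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for wav in sorted(wav_dir.glob("*.wav")):
        clip = read_wav(wav)
        preds = predict_file(model, clip, preproc)
        track = windows_to_frames(preds, clip.duration_s, threshold=threshold,
                                  segment_s=preproc.segment_s)
        events = frames_to_events(track, preds, segment_s=preproc.segment_s)
        written.append(write_events_csv(out_dir / f"{wav.stem}.csv", events, wav.stem))
    return written


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: dict, out_dir) -> dict:
    """Execute the full study emulation; returns (and writes) the manifest."""
    required = {"seed", "benchmark", "preprocessing", "training", "detection", "behaviour"}
    missing = required - set(config)
    if missing:
        raise KeyError(f"config is missing required section(s): {sorted(missing)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest = {
        "package_version": __version__,
        "started": dt.datetime.now().isoformat(timespec="seconds"),
        "config": config,
        "stages": {},
    }

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    bench_dir = out_dir / "benchmark"
    stage("synth", lambda: synth_benchmark(
        bench_dir, seed=seed, overwrite=True, **config["benchmark"]))
    manifest["stages"]["synth"] = sorted(str(p.relative_to(out_dir)) for p in bench_dir.rglob("*.*"))

    preproc = PreprocConfig(**config["preprocessing"])
    tc = TrainConfig(seed=seed, **config["training"])
    model, history, data_hash = stage(
        "train", lambda: train_on_benchmark(bench_dir, tc, preproc))
    ckpt = out_dir / "model.ckpt"
    save_checkpoint(ckpt, model, tc, data_hash)
    (out_dir / "train_history.json").write_text(json.dumps(history, indent=2))
    manifest["stages"]["train"] = {"checkpoint": str(ckpt.name), "dataset_hash": data_hash,
                                   "final_loss": history["loss"][-1] if history["loss"] else None}

    events_dir = out_dir / "events"
    stage("detect", lambda: detect_directory(
        model, bench_dir / "test", events_dir, preproc,
        threshold=config["detection"]["threshold"]))

    table = stage("evaluate", lambda: evaluate_files(bench_dir / "test", events_dir))
    table.to_csv(out_dir / "metrics.csv", index=False)
    pooled = table[table["file"] == "pooled"].iloc[0]
    manifest["stages"]["evaluate"] = {k: float(pooled[k]) for k in ("recall", "precision", "accuracy", "f1")}

    bcfg = dict(config["behaviour"])
    n_records = bcfg.pop("n_records", None)
    params = BehaviourParams(seed=seed, **bcfg)
    records = stage("behaviour", lambda: synth_behaviour_series(params, n_records=n_records))
    records.to_csv(out_dir / "records.csv", index=False)
    fit = stage("analyze", lambda: fit_hgam(records, HGAMSpec()))
    (out_dir / "fit_summary.json").write_text(json.dumps(fit.summary(), indent=2))
    curves = predict_smooths(fit)
    curves["hour"].to_csv(out_dir / "smooth_hour.csv", index=False)
    curves["day"].to_csv(out_dir / "smooth_day.csv", index=False)
    diag = diagnostics(fit, records)
    diag["table"].to_csv(out_dir / "diagnostics.csv", index=False)
    manifest["stages"]["analyze"] = {
        "status_contrast": fit.status_contrast,
        "deviance_explained": fit.deviance_explained,
        "wilcoxon": {k: v for k, v in status_contrast_test(records).items() if k in ("W", "p")},
    }

    manifest["hashes"] = {
        str(p.relative_to(out_dir)): _sha256(p)
        for p in sorted(out_dir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest["finished"] = dt.datetime.now().isoformat(timespec="seconds")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
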