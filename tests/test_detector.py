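import numpy as np
import pytest

from rutvox.audio_io import AudioClip
from rutvox.detector import (
    DetectionEvent,
    TrainConfig,
    WindowPrediction,
    build_model,
    frames_to_events,
    load_checkpoint,
    predict_file,
    save_checkpoint,
    train,
    windows_to_frames,
)
from rutvox.nnet import CompactCNN
from rutvox.preprocessing import PreprocConfig


def toy_dataset(n=48, seed=0, shape=(128, 126, 3)):
    """Two constant-texture classes that are trivially separable."""
    rng = np.random.default_rng(seed)
    X0 = rng.uniform(0.0, 0.3, (n, *shape)).astype(np.float32)
    stripe = (np.arange(shape[0]) % 8 < 2).astype(np.float32)[:, None, None]
    X1 = np.clip(rng.uniform(0.0, 0.3, (n, *shape)) + 0.6 * stripe, 0, 1).astype(np.float32)
    X = np.concatenate([X0, X1])
    y = np.concatenate([np.zeros(n, int), np.ones(n, int)])
    return X, y


class TestBuildModel:
    def test_two_way_output_with_unit_probabilities(self):
        model = build_model(TrainConfig(seed=0))
        X = np.random.default_rng(1).uniform(0, 1, (3, 128, 126, 3)).astype(np.float32)
        p = model.predict_proba(X)
        assert p.shape == (3, 2)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-5)
        assert model.n_parameters > 0

    def test_same_seed_gives_identical_initial_parameters(self):
        a = build_model(TrainConfig(seed=3)).named_parameters()
        b = build_model(TrainConfig(seed=3)).named_parameters()
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_shape_mismatch_rejected(self):
        model = build_model(TrainConfig(seed=0))
        with pytest.raises(ValueError, match="shape"):
            model.forward(np.zeros((1, 64, 64, 3), dtype=np.float32))

    def test_pretrained_backbone_unavailable(self):
        with pytest.raises(NotImplementedError):
            build_model(TrainConfig(backbone="pretrained-image-backbone"))


class TestGradients:
    def test_analytic_gradient_matches_finite_differences(self):
        model = CompactCNN((16, 14, 2), channels=(3,), hidden=4, seed=0)
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, (4, 16, 14, 2)).astype(np.float32)
        y = np.array([0, 1, 0, 1])

        def loss_at(params):
            model.set_parameters(params)
            logits = model.forward(X)
            z = logits - logits.max(axis=1, keepdims=True)
            logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
            return -logp[np.arange(4), y].mean()

        # analytic gradients via a train step with zero learning rate
        from rutvox.nnet import AdamState, softmax

        base = {k: v.copy() for k, v in model.named_parameters().items()}
        model.train_step(X, y, AdamState(lr=0.0))
        analytic = {}
        for i, layer in enumerate(model._all_layers()):
            if hasattr(layer, "grads"):
                for k, g in layer.grads().items():
                    analytic[f"layer{i}.{k}"] = g.copy()
        eps = 1e-3
        rng_idx = np.random.default_rng(0)
        for name in ["layer1.W", "layer5.W", "layer7.b"]:
            flat = base[name].ravel()
            for j in rng_idx.choice(flat.size, size=min(3, flat.size), replace=False):
                pert = {k: v.copy() for k, v in base.items()}
                pert[name] = pert[name].copy()
                pert[name].ravel()[j] += eps
                up = loss_at(pert)
                pert[name].ravel()[j] -= 2 * eps
                down = loss_at(pert)
                fd = (up - down) / (2 * eps)
                an = analytic[name].ravel()[j]
                assert abs(fd - an) < 5e-3 * max(1.0, abs(an)), (name, j, fd, an)


class TestTraining:
    def test_zero_epochs_leaves_weights_unchanged(self):
        model = build_model(TrainConfig(seed=1))
        before = {k: v.copy() for k, v in model.named_parameters().items()}
        X, y = toy_dataset(8)
        train(model, (X, y), TrainConfig(epochs=0, seed=1))
        after = model.named_parameters()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_separable_classes_learned_within_10_epochs(self):
        model = build_model(TrainConfig(seed=1))
        X, y = toy_dataset(48)
        history = train(model, (X, y), TrainConfig(epochs=10, seed=1))
        assert max(history["accuracy"]) >= 0.99

    def test_training_is_deterministic(self):
        X, y = toy_dataset(16)
        losses = []
        for _rep in range(2):
            model = build_model(TrainConfig(seed=2))
            h = train(model, (X, y), TrainConfig(epochs=2, seed=2))
            losses.append(h["loss"][-1])
        assert abs(losses[0] - losses[1]) < 1e-6

    def test_empty_dataset_rejected(self):
        model = build_model(TrainConfig(seed=0))
        with pytest.raises(ValueError, match="empty"):
            train(model, [], TrainConfig(epochs=1))


@pytest.fixture(scope="module")
def model():
    return build_model(TrainConfig(seed=0))


class TestPredictFile:

    def test_10s_file_gives_7_windows(self, model):
        clip = AudioClip(np.random.default_rng(0).uniform(-0.1, 0.1, 80000), 8000)
        preds = predict_file(model, clip)
        assert [p.window_start_s for p in preds] == [0, 1, 2, 3, 4, 5, 6]

    def test_4s_file_gives_single_window(self, model):
        clip = AudioClip(np.zeros(32000), 8000)
        assert len(predict_file(model, clip)) == 1

    def test_sub_second_clip_gives_single_padded_window(self, model):
        clip = AudioClip(np.zeros(4000), 8000)
        assert len(predict_file(model, clip)) == 1

    def test_batch_partitioning_does_not_change_predictions(self, model):
        clip = AudioClip(np.random.default_rng(1).uniform(-0.1, 0.1, 96000), 8000)
        a = predict_file(model, clip, batch_size=64)
        b = predict_file(model, clip, batch_size=3)
        assert np.allclose([p.p_presence for p in a], [p.p_presence for p in b], atol=1e-6)


def _preds(positive_starts, n=10):
    return [
        WindowPrediction(s, 0.9 if s in positive_starts else 0.1,
                         0.1 if s in positive_starts else 0.9)
        for s in range(n - 3)
    ]


class TestWindowsToFrames:
    def test_coverage_union_worked_example(self):
        track = windows_to_frames(_preds({2, 3}), file_duration_s=10)
        assert list(np.where(track)[0]) == [2, 3, 4, 5, 6]

    def test_no_positive_windows_gives_empty_track(self):
        assert not windows_to_frames(_preds(set()), 10).any()

    def test_all_positive_windows_cover_everything(self):
        track = windows_to_frames(_preds(set(range(7))), 10)
        assert track.all()

    def test_agrees_with_coverage_union_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(5, 30))
            pos = {int(s) for s in rng.choice(n - 3, size=rng.integers(0, n - 3), replace=False)}
            track = windows_to_frames(_preds(pos, n), n)
            # oracle: frame positive iff any positive window [s, s+4) overlaps it
            expect = np.zeros(n, dtype=bool)
            for f in range(n):
                expect[f] = any(s < f + 1 and s + 4 > f for s in pos)
            assert np.array_equal(track, expect)

    def test_majority_rule_stricter_than_any(self):
        any_track = windows_to_frames(_preds({2}), 10, rule="any")
        maj_track = windows_to_frames(_preds({2}), 10, rule="majority")
        assert any_track.sum() >= maj_track.sum()


class TestFramesToEvents:
    def test_single_run_becomes_single_event(self):
        track = np.zeros(10, dtype=bool)
        track[2:7] = True
        events = frames_to_events(track)
        assert len(events) == 1
        assert (events[0].start_s, events[0].end_s) == (2.0, 7.0)

    def test_empty_track_gives_no_events(self):
        assert frames_to_events(np.zeros(5, dtype=bool)) == []

    def test_alternating_frames_give_one_event_each(self):
        track = np.array([True, False] * 4)
        events = frames_to_events(track)
        assert len(events) == 4
        assert all(e.end_s - e.start_s == 1.0 for e in events)

    def test_event_score_averages_contributing_windows(self):
        preds = _preds({2, 3})
        track = windows_to_frames(preds, 10)
        events = frames_to_events(track, preds)
        covering = [p.p_presence for p in preds if p.window_start_s < 7 and p.window_start_s + 4 > 2]
        assert np.isclose(events[0].mean_score, np.mean(covering))


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path):
        model = build_model(TrainConfig(seed=4))
        X, y = toy_dataset(8)
        train(model, (X, y), TrainConfig(epochs=1, seed=4))
        path = save_checkpoint(tmp_path / "m.ckpt", model, TrainConfig(seed=4), "abc123")
        loaded, cfg, manifest = load_checkpoint(path)
        assert manifest == "abc123"
        assert cfg.seed == 4
        assert np.allclose(model.predict_proba(X), loaded.predict_proba(X), atol=1e-7)


def test_detector_finds_long_grunts_on_easy_benchmark(easy_benchmark, trained_easy):
    """End-to-end recall property: at high SNR every grunt series of >=2 s
    overlaps at least one detected event."""
    from rutvox.audio_io import read_boxes, read_wav

    model, _cfg, history, _h = trained_easy
    wav = sorted((easy_benchmark / "test").glob("*.wav"))[0]
    clip = read_wav(wav)
    boxes = [b for b in read_boxes(wav.with_suffix(".csv")) if b.label == "presence"]
    preds = predict_file(model, clip)
    track = windows_to_frames(preds, clip.duration_s)
    events = frames_to_events(track, preds)
    for b in boxes:
        if b.duration_s >= 2.0:
            assert any(e.start_s < b.end_s and e.end_s > b.start_s for e in events), b
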