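import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rutvox.audio_io import AnnotationBox, AudioClip
from rutvox.preprocessing import (
    PreprocConfig,
    SpectrogramTensor,
    augment_time_shift,
    balance_classes,
    expand_channels,
    low_pass,
    lowpass_response_db,
    mel_spectrogram,
    resample,
    segments_from_annotations,
    window_starts,
)

CFG = PreprocConfig()


def tone(freq, duration_s=2.0, rate=16000, amp=0.5):
    t = np.arange(int(duration_s * rate)) / rate
    return AudioClip(amp * np.sin(2 * np.pi * freq * t), rate)


def rms(clip):
    return np.sqrt(np.mean(clip.samples**2))


class TestLowPass:
    def test_passband_tone_nearly_untouched(self):
        clip = tone(50)
        assert abs(rms(low_pass(clip, 1000)) / rms(clip) - 1) < 0.01

    @pytest.mark.parametrize("freq", [1500, 3000])
    def test_stopband_attenuation_matches_filter_response(self, freq):
        # measure steady state on the central 2 s of a 6-s tone so the
        # onset/offset transients do not mask the stopband floor
        clip = tone(freq, duration_s=6.0)
        out = low_pass(clip, 1000)
        mid = slice(2 * 16000, 4 * 16000)
        measured_db = 20 * np.log10(
            np.sqrt(np.mean(out.samples[mid] ** 2)) / np.sqrt(np.mean(clip.samples[mid] ** 2))
        )
        expected_db = lowpass_response_db(1000, freq, 16000)
        assert measured_db < -50
        assert abs(measured_db - expected_db) < 0.05 * abs(expected_db)

    def test_zero_signal_stays_zero(self):
        clip = AudioClip(np.zeros(1000), 16000)
        assert not low_pass(clip, 1000).samples.any()

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            low_pass(tone(100), 8000)


class TestResample:
    def test_length_follows_duration_times_rate(self):
        out = resample(tone(100, duration_s=4.0), 8000)
        assert out.samples.size == 32000
        assert out.sample_rate_hz == 8000

    def test_tone_survives_downsampling(self):
        out = resample(tone(440, duration_s=4.0), 8000)
        mag = np.abs(np.fft.rfft(out.samples))
        freqs = np.fft.rfftfreq(out.samples.size, 1 / 8000)
        assert abs(freqs[np.argmax(mag)] - 440) <= 2.0

    def test_identity_when_rate_matches(self):
        clip = tone(100)
        out = resample(clip, 16000)
        assert np.array_equal(out.samples, clip.samples)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError, match="upsampling"):
            resample(tone(100, rate=8000), 16000)


def brute_force_starts(start, end, segment_s, stride_s):
    """Independent enumeration of the stated windowing rule."""
    starts = []
    s = start
    while s + segment_s <= end + 1e-9:
        starts.append(s)
        s += stride_s
    return starts or [start]


class TestWindowStarts:
    def box(self, start, end):
        return AnnotationBox("f", start, end, 0, 1000, "presence")

    def test_worked_example(self):
        assert window_starts(self.box(10.0, 16.5), 4, 1) == [10.0, 11.0, 12.0]

    def test_exact_fit_gives_single_start(self):
        assert window_starts(self.box(0.0, 4.0), 4, 1) == [0.0]

    def test_short_box_gives_single_start(self):
        assert window_starts(self.box(5.0, 6.0), 4, 1) == [5.0]

    def test_agrees_with_brute_force_on_random_boxes(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            start = rng.uniform(0, 50)
            end = start + rng.uniform(0.2, 40)
            stride = rng.choice([0.5, 1.0, 2.0])
            got = window_starts(self.box(start, end), 4.0, stride)
            assert np.allclose(got, brute_force_starts(start, end, 4.0, stride))


class TestSegments:
    def test_presence_box_yields_expected_tensor_count(self):
        clip, = [tone(60, duration_s=20.0)]
        boxes = [AnnotationBox("f", 2.0, 8.5, 0, 1000, "presence")]
        segs = segments_from_annotations(clip, boxes, CFG)
        assert len(segs) == 3
        assert all(s.label == "presence" for s in segs)
        assert all(s.values.shape == (128, 126, 3) for s in segs)

    def test_no_boxes_gives_empty_list(self):
        assert segments_from_annotations(tone(60), [], CFG) == []

    def test_box_beyond_file_rejected(self):
        boxes = [AnnotationBox("f", 50.0, 55.0, 0, 1000, "presence")]
        with pytest.raises(ValueError, match="beyond"):
            segments_from_annotations(tone(60, duration_s=10.0), boxes, CFG)

    def test_window_overrunning_eof_is_padded(self):
        boxes = [AnnotationBox("f", 8.0, 9.5, 0, 1000, "presence")]
        segs = segments_from_annotations(tone(60, duration_s=10.0), boxes, CFG)
        assert len(segs) == 1
        assert segs[0].values.shape == (128, 126, 3)


class TestAugmentAndBalance:
    def _segments(self, n, label="presence"):
        clip = tone(60, duration_s=30.0)
        boxes = [
            AnnotationBox("f", 2.0 + 5 * i, 2.0 + 5 * i + 4.0, 0, 1000, label)
            for i in range(n)
        ]
        return segments_from_annotations(clip, boxes, CFG), clip

    def test_augments_to_target_count(self):
        segs, clip = self._segments(5)
        out = augment_time_shift(segs, 9, seed=0, audio_by_file={"f": clip}, config=CFG)
        assert len(out) == 9
        assert all(s.label == "presence" for s in out)

    def test_target_below_current_is_noop(self):
        segs, clip = self._segments(5)
        out = augment_time_shift(segs, 3, seed=0, audio_by_file={"f": clip}, config=CFG)
        assert out == segs

    def test_augment_deterministic_under_seed(self):
        segs, clip = self._segments(4)
        a = augment_time_shift(segs, 8, seed=5, audio_by_file={"f": clip}, config=CFG)
        b = augment_time_shift(segs, 8, seed=5, audio_by_file={"f": clip}, config=CFG)
        assert [s.source for s in a] == [s.source for s in b]
        assert all(np.array_equal(x.values, y.values) for x, y in zip(a, b))

    def test_balance_subsamples_majority(self):
        pres, clip = self._segments(3)
        abs_, _ = self._segments(5, label="absence")
        p, a = balance_classes(pres, abs_, seed=1)
        assert len(p) == len(a) == 3
        p2, a2 = balance_classes(pres, abs_, seed=1)
        assert [s.source for s in a2] == [s.source for s in a]

    def test_balance_rejects_empty_class(self):
        pres, _ = self._segments(2)
        with pytest.raises(ValueError, match="non-empty"):
            balance_classes(pres, [], seed=0)


class TestMelSpectrogram:
    def segment(self, freq=200):
        t = np.arange(32000) / 8000
        return AudioClip(0.4 * np.sin(2 * np.pi * freq * t), 8000)

    def test_shape_follows_config(self):
        m = mel_spectrogram(self.segment(), CFG)
        assert m.shape == (128, 32000 // 256 + 1)
        assert m.shape == (128, 126)

    def test_values_normalized_to_unit_interval(self):
        m = mel_spectrogram(self.segment(), CFG)
        assert m.min() == 0.0 and m.max() == 1.0

    def test_silence_maps_to_zeros(self):
        m = mel_spectrogram(AudioClip(np.zeros(32000), 8000), CFG)
        assert not m.any()

    def test_wrong_rate_rejected(self):
        seg = AudioClip(np.zeros(64000), 16000)
        with pytest.raises(ValueError, match="rate"):
            mel_spectrogram(seg, CFG)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            mel_spectrogram(AudioClip(np.zeros(1000), 8000), CFG)


class TestExpandChannels:
    def test_exponent_arithmetic(self):
        out = expand_channels(np.array([[0.5]]))
        assert np.allclose(out.ravel(), [0.5, 0.125, 0.03125])

    def test_fixed_points(self):
        out = expand_channels(np.array([[0.0, 1.0]]))
        assert np.array_equal(out[0, 0], [0, 0, 0])
        assert np.array_equal(out[0, 1], [1, 1, 1])

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_channels_monotone_decreasing(self, seed):
        x = np.random.default_rng(seed).uniform(0, 1, (8, 8))
        out = expand_channels(x)
        assert np.all(out[..., 2] <= out[..., 1] + 1e-12)
        assert np.all(out[..., 1] <= out[..., 0] + 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            expand_channels(np.array([[1.5]]))


def test_pipeline_is_deterministic():
    clip = tone(60, duration_s=12.0)
    boxes = [AnnotationBox("f", 1.0, 9.0, 0, 1000, "presence")]
    a = segments_from_annotations(clip, boxes, CFG)
    b = segments_from_annotations(clip, boxes, CFG)
    assert all(np.array_equal(x.values, y.values) for x, y in zip(a, b))
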