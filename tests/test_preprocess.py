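"""Preprocessing tests: filter response, segmentation grids, rejection rules."""

import numpy as np
import pandas as pd
import pytest

from nlrpipe.errors import InvalidConfigError, PipelineError
from nlrpipe.preprocess import (
    EpochsSet,
    average_reference,
    bandpass_filter,
    baseline_correct,
    preprocess_recording,
    reject_high_range,
    rejection_log,
    resample_epochs,
    roi_average,
    segment,
)
from nlrpipe.stimgen import assign_timing
from nlrpipe.synth_eeg import (
    ROI_CHANNEL_IDS,
    ContinuousRecording,
    default_channel_ids,
    simulate_recording,
)


def _sine_recording(freq_hz, duration_s=20.0, sfreq=250.0, n_channels=2, amp=1.0):
    t = np.arange(int(duration_s * sfreq)) / sfreq
    data = np.tile(amp * np.sin(2 * np.pi * freq_hz * t), (n_channels, 1))
    events = pd.DataFrame(
        {"trial": [0], "sample": [int(5 * sfreq)], "onset_s": [5.0],
         "frequency_hz": [600.0], "source_set": ["reference"]}
    )
    return ContinuousRecording(data, sfreq, default_channel_ids(max(n_channels, 12))[:n_channels]
                               if n_channels >= 12 else tuple(f"E{i}" for i in range(1, n_channels + 1)),
                               events)


def _epochs(data, sfreq=250.0, t0_ms=-300.0):
    """EpochsSet straight from an array (n_trials, n_channels, n_times)."""
    n_trials, n_channels, n_times = data.shape
    times = t0_ms + np.arange(n_times) * 1000.0 / sfreq
    events = pd.DataFrame(
        {"trial": np.arange(n_trials), "sample": np.zeros(n_trials, dtype=int),
         "onset_s": np.arange(n_trials, dtype=float),
         "frequency_hz": np.full(n_trials, 600.0),
         "source_set": np.full(n_trials, "reference", dtype=object)}
    )
    ids = tuple(ROI_CHANNEL_IDS[:n_channels]) if n_channels <= 11 else tuple(
        default_channel_ids(n_channels)
    )
    return EpochsSet(data, times, sfreq, ids, events, np.ones((n_trials, n_channels), bool))


class TestFilter:
    def test_stopband_attenuation_50hz(self):
        rec = _sine_recording(50.0)
        out = bandpass_filter(rec)
        mid = slice(1000, 4000)  # avoid edge transients
        assert np.abs(out.data_uv[0, mid]).max() < 0.1

    def test_passband_preserves_10hz(self):
        rec = _sine_recording(10.0)
        out = bandpass_filter(rec)
        mid = slice(1000, 4000)
        assert np.abs(out.data_uv[0, mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_dc_removed(self):
        rec = _sine_recording(10.0)
        rec.data_uv[:] = 7.5
        out = bandpass_filter(rec)
        assert np.abs(out.data_uv[:, 1000:4000]).max() < 0.05

    def test_invalid_band(self):
        rec = _sine_recording(10.0)
        with pytest.raises(InvalidConfigError):
            bandpass_filter(rec, 30.0, 0.3)
        with pytest.raises(InvalidConfigError):
            bandpass_filter(rec, 0.3, 200.0)  # above Nyquist at 250 Hz


class TestSegment:
    def test_one_epoch_per_marker(self):
        rng = np.random.default_rng(0)
        sfreq = 250.0
        data = rng.standard_normal((2, int(700 * sfreq)))
        onsets = 2.0 + np.arange(620) * 1.1
        events = pd.DataFrame(
            {"trial": np.arange(620), "sample": (onsets * sfreq).astype(int),
             "onset_s": onsets, "frequency_hz": 600.0, "source_set": "reference"}
        )
        rec = ContinuousRecording(data, sfreq, ("E1", "E2"), events)
        epochs = segment(rec)
        assert epochs.n_trials == 620
        assert epochs.data_uv.shape[2] == 326  # -300..1000 ms at 4 ms steps
        assert epochs.times_ms[0] == -300.0 and epochs.times_ms[-1] == 1000.0

    def test_edge_marker_dropped(self):
        sfreq = 250.0
        data = np.zeros((2, int(10 * sfreq)))
        events = pd.DataFrame(
            {"trial": [0, 1], "sample": [int(0.1 * sfreq), int(5 * sfreq)],
             "onset_s": [0.1, 5.0], "frequency_hz": 600.0, "source_set": "reference"}
        )
        rec = ContinuousRecording(data, sfreq, ("E1", "E2"), events)
        epochs = segment(rec)
        assert epochs.n_trials == 1
        assert list(epochs.events["trial"]) == [1]

    def test_no_epochs_error(self):
        sfreq = 250.0
        data = np.zeros((2, 100))
        events = pd.DataFrame(
            {"trial": [0], "sample": [0], "onset_s": [0.0],
             "frequency_hz": 600.0, "source_set": "reference"}
        )
        rec = ContinuousRecording(data, sfreq, ("E1", "E2"), events)
        with pytest.raises(PipelineError):
            segment(rec)


class TestBaseline:
    def test_pre_interval_mean_zero(self):
        rng = np.random.default_rng(1)
        epochs = baseline_correct(_epochs(rng.standard_normal((5, 3, 326))))
        pre = (epochs.times_ms >= -300) & (epochs.times_ms < 0)
        np.testing.assert_allclose(epochs.data_uv[:, :, pre].mean(axis=2), 0.0, atol=1e-12)

    def test_constant_becomes_zero(self):
        epochs = baseline_correct(_epochs(np.full((2, 2, 326), 3.3)))
        np.testing.assert_allclose(epochs.data_uv, 0.0, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        once = baseline_correct(_epochs(rng.standard_normal((4, 2, 326))))
        twice = baseline_correct(once)
        np.testing.assert_allclose(twice.data_uv, once.data_uv, atol=1e-12)


class TestResample:
    def test_grid_250_to_100(self):
        epochs = resample_epochs(_epochs(np.zeros((2, 2, 326))), 100.0)
        assert epochs.data_uv.shape[2] == 131
        assert epochs.times_ms[0] == -300.0
        np.testing.assert_allclose(np.diff(epochs.times_ms), 10.0)

    def test_bandlimited_preserved(self):
        t = -0.3 + np.arange(326) / 250.0
        wave = np.sin(2 * np.pi * 5.0 * t)
        epochs = resample_epochs(_epochs(np.tile(wave, (1, 2, 1))), 100.0)
        t_new = epochs.times_ms / 1000.0
        expected = np.sin(2 * np.pi * 5.0 * t_new)
        mid = slice(10, 120)  # polyphase edges excluded
        rms = np.sqrt(np.mean((epochs.data_uv[0, 0, mid] - expected[mid]) ** 2))
        assert rms < 0.02 * np.sqrt(np.mean(expected[mid] ** 2)) * np.sqrt(2) + 0.02

    def test_identity_and_upsample_error(self):
        epochs = _epochs(np.zeros((1, 2, 326)))
        assert resample_epochs(epochs, 250.0) is epochs
        with pytest.raises(InvalidConfigError):
            resample_epochs(epochs, 500.0)


class TestAverageReference:
    def test_channel_mean_zero(self):
        rng = np.random.default_rng(3)
        out = average_reference(_epochs(rng.standard_normal((3, 4, 50))))
        np.testing.assert_allclose(out.data_uv.mean(axis=1), 0.0, atol=1e-12)

    def test_antisymmetric_pair_unchanged(self):
        v = np.random.default_rng(4).standard_normal((1, 1, 50))
        data = np.concatenate([v, -v], axis=1)
        out = average_reference(_epochs(data))
        np.testing.assert_allclose(out.data_uv, data, atol=1e-12)

    def test_idempotent_and_min_channels(self):
        rng = np.random.default_rng(5)
        once = average_reference(_epochs(rng.standard_normal((2, 3, 50))))
        twice = average_reference(once)
        np.testing.assert_allclose(twice.data_uv, once.data_uv, atol=1e-12)
        with pytest.raises(InvalidConfigError):
            average_reference(_epochs(np.zeros((1, 1, 50))))


class TestRejection:
    def test_threshold_boundary(self):
        data = np.zeros((1, 2, 326))
        data[0, 0, 10] = 101.0  # range 101 -> masked
        data[0, 1, 10] = 100.0  # range exactly 100 -> retained
        out = reject_high_range(_epochs(data))
        assert not out.mask[0, 0]
        assert out.mask[0, 1]

    def test_log_format(self):
        data = np.zeros((2, 2, 326))
        data[0, 0, 5] = 150.0
        out = reject_high_range(_epochs(data))
        log = rejection_log(out)
        assert list(log.columns) == ["trial", "channel", "range_uv", "masked"]
        assert log["masked"].sum() == 1


class TestRoiAverage:
    def _roi_epochs(self, data, mask=None):
        epochs = _epochs(data)
        if mask is not None:
            epochs.mask[:] = mask
        return epochs

    def test_identical_channels(self):
        rng = np.random.default_rng(6)
        trace = rng.standard_normal((3, 1, 50))
        data = np.repeat(trace, 12, axis=1)
        roi = roi_average(self._roi_epochs(data))
        np.testing.assert_allclose(roi.data_uv, trace[:, 0, :], atol=1e-12)
        assert roi.retained.all()

    def test_min_channel_rule(self):
        data = np.zeros((2, 12, 50))
        mask = np.ones((2, 12), bool)
        mask[0, :5] = False  # 6 of 11 ROI channels left -> retained
        mask[1, :6] = False  # 5 of 11 left -> excluded
        roi = roi_average(self._roi_epochs(data, mask))
        assert roi.retained[0]
        assert not roi.retained[1]
        assert roi.n_channels_retained[0] == 6

    def test_missing_roi_channel(self):
        epochs = _epochs(np.zeros((1, 4, 50)))  # only 4 ROI ids present
        with pytest.raises(InvalidConfigError, match="missing"):
            roi_average(epochs)


class TestFullChain:
    def test_transfer_factor_stable_across_trials(self, noise_free, narrow_dist, clean_subject):
        seq = assign_timing(
            np.full(6, 600.0), np.full(6, "reference", dtype=object),
            isi_range_ms=(1400, 1400), seed=0,
        )
        rec = simulate_recording(seq, clean_subject, noise_free, narrow_dist, seed=0, n_channels=12)
        roi = preprocess_recording(rec)
        i_n1 = roi.sample_index(clean_subject.n1_latency_ms)
        i_p2 = roi.sample_index(clean_subject.p2_latency_ms)
        factors = roi.data_uv[:, i_p2] - roi.data_uv[:, i_n1]
        assert factors.std() < 1e-3 * np.abs(factors.mean())
        assert 0.8 < factors.mean() / clean_subject.baseline_gain_uV < 1.1

    def test_unknown_preset(self, noise_free, narrow_dist, clean_subject):
        seq = assign_timing(np.full(3, 600.0), np.full(3, "reference", dtype=object), seed=0)
        rec = simulate_recording(seq, clean_subject, noise_free, narrow_dist, seed=0, n_channels=12)
        with pytest.raises(InvalidConfigError):
            preprocess_recording(rec, preset="fancy")

    def test_robustness_preset_keeps_250hz(self, noise_free, narrow_dist, clean_subject):
        seq = assign_timing(np.full(3, 600.0), np.full(3, "reference", dtype=object), seed=0)
        rec = simulate_recording(seq, clean_subject, noise_free, narrow_dist, seed=0, n_channels=12)
        roi = preprocess_recording(rec, preset="robustness")
        assert roi.sfreq_hz == 250.0
        assert roi.data_uv.shape[1] == 326
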