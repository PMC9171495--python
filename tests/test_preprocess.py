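"""Preprocessing-chain tests: filtering, referencing, epoching, artifact
rejection, resampling, montage selection, and their interactions."""

import numpy as np
import pytest
from scipy.signal import periodogram

from conftest import make_trialset
from tvconn.containers import Recording
from tvconn.preprocess import (bandpass, downsample, epoch, reject_artifacts,
                               rereference, select_channels)


def rms(x):
    return np.sqrt(np.mean(x ** 2))


class TestBandpass:
    def test_stopband_and_passband_response(self, sine_recording):
        out = bandpass(sine_recording, 8.0, 30.0)
        # steady-state response, edges trimmed
        sl = slice(2000, -2000)
        assert rms(out.data[0, sl]) <= 0.10 * rms(sine_recording.data[0, sl])  # 5 Hz
        assert rms(out.data[1, sl]) == pytest.approx(
            rms(sine_recording.data[1, sl]), rel=0.05)  # 15 Hz

    def test_zero_input_zero_output(self):
        rec = Recording(np.zeros((2, 5000)), 1000.0, ["a", "b"])
        assert np.all(bandpass(rec).data == 0)

    def test_band_outside_nyquist_rejected(self):
        rec = Recording(np.zeros((2, 5000)), 100.0, ["a", "b"])
        with pytest.raises(ValueError):
            bandpass(rec, 8.0, 60.0)


class TestRereference:
    def test_average_reference_zeroes_channel_mean(self):
        rng = np.random.default_rng(0)
        rec = Recording(rng.standard_normal((5, 1000)), 100.0, list("abcde"))
        out = rereference(rec, "average")
        assert np.allclose(out.data.mean(axis=0), 0.0, atol=1e-12)

    def test_average_reference_idempotent(self):
        rng = np.random.default_rng(1)
        rec = Recording(rng.standard_normal((4, 500)), 100.0, list("abcd"))
        once = rereference(rec, "average")
        twice = rereference(once, "average")
        assert np.allclose(once.data, twice.data)

    def test_one_hot_weights_subtract_that_channel(self):
        rng = np.random.default_rng(2)
        rec = Recording(rng.standard_normal((3, 400)), 100.0, list("abc"))
        w = np.array([0.0, 1.0, 0.0])
        out = rereference(rec, "custom", weights=w)
        assert np.allclose(out.data, rec.data - rec.data[1])

    def test_single_channel_rejected(self):
        rec = Recording(np.zeros((1, 100)), 100.0, ["a"])
        with pytest.raises(ValueError):
            rereference(rec, "average")


class TestEpoch:
    @staticmethod
    def _recording_with_events(n_events=70, fs=1000.0):
        rng = np.random.default_rng(3)
        gap = int(11 * fs)
        n = int((n_events + 2) * 11 * fs)
        data = rng.standard_normal((2, n))
        events = [(int(4 * fs) + i * gap, "left" if i % 2 else "right")
                  for i in range(n_events)]
        return Recording(data, fs, ["a", "b"], events)

    def test_event_count_preserved(self):
        rec = self._recording_with_events(70)
        ts = epoch(rec, (-4.0, 6.0))
        assert ts.n_trials == 70

    def test_trial_length_closed_left_open_right(self):
        rec = self._recording_with_events(3)
        ts = epoch(rec, (-4.0, 6.0))
        assert ts.n_samples == 10_000
        assert ts.times[0] == pytest.approx(-4.0)
        assert ts.times[-1] == pytest.approx(6.0 - 1 / rec.fs)

    def test_event_at_recording_start_skipped(self):
        rec = self._recording_with_events(3)
        rec.events.insert(0, (0, "left"))
        ts = epoch(rec, (-4.0, 6.0))
        assert ts.n_trials == 3


class TestRejectArtifacts:
    def test_spike_above_threshold_rejected(self):
        data = np.full((2, 3, 100), 10.0)
        data[0, 1, 50] = 80.0
        ts = make_trialset(data)
        out = reject_artifacts(ts, 70.0)
        assert out.n_trials == 1
        assert list(out.rejected_mask) == [True, False]

    def test_amplitude_below_threshold_retained(self):
        data = np.full((1, 2, 100), 69.0)
        out = reject_artifacts(make_trialset(data), 70.0)
        assert out.n_trials == 1

    def test_planted_artifact_count(self):
        rng = np.random.default_rng(4)
        data = 10.0 * rng.standard_normal((20, 3, 200)).clip(-5, 5)
        bad = [2, 7, 13]
        for k in bad:
            data[k, 0, 10] = 100.0
        out = reject_artifacts(make_trialset(data), 70.0)
        assert out.n_trials == 17
        assert sorted(np.flatnonzero(out.rejected_mask)) == bad

    def test_all_rejected_is_an_error(self):
        data = np.full((3, 2, 50), 200.0)
        with pytest.raises(ValueError, match="no data survives"):
            reject_artifacts(make_trialset(data), 70.0)

    def test_rejection_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        data = 22.0 * rng.standard_normal((30, 2, 100))
        ts = make_trialset(data)
        strict = reject_artifacts(ts, 60.0)
        loose = reject_artifacts(ts, 90.0)
        # every trial rejected at the loose threshold is rejected at the strict one
        assert np.all(strict.rejected_mask | ~loose.rejected_mask)


class TestDownsample:
    def test_decimation_count(self):
        data = np.zeros((2, 3, 10_000))
        ts = make_trialset(data, fs=1000.0)
        out = downsample(ts, 100.0)
        assert out.n_samples == 1000
        assert out.fs == 100.0
        assert out.times[0] == pytest.approx(ts.times[0])

    def test_identity_when_rates_match(self):
        ts = make_trialset(np.zeros((1, 2, 100)), fs=100.0)
        assert downsample(ts, 100.0) is ts

    def test_upsampling_rejected(self):
        ts = make_trialset(np.zeros((1, 2, 100)), fs=100.0)
        with pytest.raises(ValueError):
            downsample(ts, 200.0)

    def test_spectral_peak_preserved(self):
        fs = 1000.0
        t = np.arange(10_000) / fs
        data = np.sin(2 * np.pi * 12 * t)[None, None, :]
        out = downsample(make_trialset(data, fs=fs), 100.0)
        f, p = periodogram(out.data[0, 0], fs=100.0)
        assert f[np.argmax(p)] == pytest.approx(12.0, abs=0.2)


class TestSelectChannels:
    def test_subset_in_requested_order(self):
        data = np.arange(4 * 100, dtype=float).reshape(1, 4, 100)
        ts = make_trialset(data)
        out = select_channels(ts, ["ch3", "ch1"])
        assert tuple(out.channel_labels) == ("ch3", "ch1")
        assert np.allclose(out.data[0, 0], ts.data[0, 2])

    def test_identity_montage(self):
        ts = make_trialset(np.zeros((1, 3, 50)))
        out = select_channels(ts, ["ch1", "ch2", "ch3"])
        assert np.allclose(out.data, ts.data)

    def test_missing_channel_named_in_error(self):
        ts = make_trialset(np.zeros((1, 3, 50)))
        with pytest.raises(KeyError, match="C5"):
            select_channels(ts, ["ch1", "C5"])

    def test_selection_commutes_with_rejection(self):
        rng = np.random.default_rng(6)
        data = 10.0 * rng.standard_normal((10, 4, 100))
        data[3, 0, 0] = 500.0  # artifact on a channel we will drop
        data[5, 2, 0] = 500.0  # artifact on a kept channel
        ts = make_trialset(data)
        keep = ["ch2", "ch3"]
        a = reject_artifacts(select_channels(ts, keep), 70.0)
        # restricted to the kept channels: the artifact on the dropped
        # channel must not cost trial 3, while trial 5's must still reject
        assert not a.rejected_mask[3]
        assert a.rejected_mask[5]
        assert np.allclose(a.data, select_channels(ts, keep).data[~a.rejected_mask])
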