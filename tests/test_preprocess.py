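"""Preprocessing contracts: epoch geometry, filter responses, artifact
screening behavior, ICA cleanup and the fixed-order full chain."""
from __future__ import annotations

import numpy as np
import pytest

import assrkit as ak
from assrkit.containers import ChannelInfo, ContinuousRecording, Event
from assrkit.preprocess import (PreprocessParams, bandpass, detect_muscle_trials,
                                detect_variance_outliers, epoch, filter_array,
                                ica_clean, notch_filter, rereference_average,
                                resample, run_preprocessing)
from assrkit.synthgen import modality_preset, simulate_session

from conftest import make_epochs

FS = 500.0


def recording_with_events(n_ch=3, fs=FS, dur_s=30.0, onsets_s=(10.0,), modality="SQUID"):
    n = int(dur_s * fs)
    chs = [ChannelInfo(f"C{i}", modality) for i in range(n_ch)]
    evs = [Event(int(o * fs), "40Hz") for o in onsets_s]
    data = np.arange(n_ch * n, dtype=float).reshape(n_ch, n)
    return ContinuousRecording(data, fs, chs, evs)


class TestEpoch:
    def test_index_arithmetic(self):
        rec = recording_with_events(onsets_s=(10.0,))
        ep = epoch(rec)
        # event at t=10 s, fs=500 -> samples 4500..6499
        np.testing.assert_array_equal(ep.data[0], rec.data[:, 4500:6500])
        assert ep.n_samples == 2000
        assert ep.time_axis_s[0] == -1.0
        assert ep.time_axis_s[int(FS)] == 0.0

    def test_simulated_session_keeps_only_40hz(self):
        cfg = modality_preset("OPM", n_channels=8, sampling_rate_hz=500.0, seed=4,
                              n_trials_per_condition={"40Hz": 20, "20Hz": 2, "60Hz": 2})
        ep = epoch(simulate_session(cfg))
        assert ep.n_trials == 20
        assert set(ep.condition_labels) == {"40Hz"}

    def test_event_near_edge_raises(self):
        rec = recording_with_events(onsets_s=(0.5,))
        with pytest.raises(ValueError, match="250"):
            epoch(rec)


class TestResample:
    def test_ratio_8(self):
        data = np.random.default_rng(0).standard_normal((2, 3, 16000))
        ep = make_epochs(data, fs=4000.0)
        out = resample(ep, 500.0)
        assert out.n_samples == 2000
        assert out.sampling_rate_hz == 500.0
        assert out.time_axis_s[int(500)] == 0.0

    def test_40hz_amplitude_preserved(self):
        # FFT oracle: amplitude at 40 Hz survives 4 kHz -> 500 Hz decimation
        fs = 4000.0
        t = (np.arange(16000) - 4000) / fs
        sine = np.sin(2 * np.pi * 40 * t)
        ep = make_epochs(sine[None, None, :], fs=fs)
        out = resample(ep, 500.0)
        seg = out.data[0, 0, 600:1600]
        spec = 2 * np.abs(np.fft.rfft(seg)) / seg.size
        freqs = np.fft.rfftfreq(seg.size, 1 / 500.0)
        amp = spec[np.argmin(abs(freqs - 40))]
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_identity_and_upsampling_guard(self):
        ep = make_epochs(np.zeros((1, 1, 2000)))
        assert resample(ep, FS) is ep
        with pytest.raises(ValueError):
            resample(ep, 1000.0)


class TestRereference:
    def test_scalp_mean_is_zero(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((4, 6, 100))
        ep = make_epochs(data, modality="EEG", tags=["frontal"] * 5 + ["eog"])
        out = rereference_average(ep)
        mean = out.data[:, :5, :].mean(axis=1)
        assert np.abs(mean).max() < 1e-12
        # EOG channel untouched
        np.testing.assert_array_equal(out.data[:, 5, :], data[:, 5, :])

    def test_constant_offset_removed(self):
        ep = make_epochs(np.full((1, 4, 50), 7.3), modality="EEG")
        out = rereference_average(ep)
        assert np.abs(out.data).max() < 1e-12

    def test_magnetic_modality_rejected(self):
        with pytest.raises(ValueError):
            rereference_average(make_epochs(np.zeros((1, 4, 50)), modality="OPM"))


class TestFilters:
    def _sine(self, f, fs=FS, n=2000):
        return np.sin(2 * np.pi * f * np.arange(n) / fs)

    def test_notch_attenuates_50_not_40(self):
        s50 = make_epochs(self._sine(50.0)[None, None, :])
        s40 = make_epochs(self._sine(40.0)[None, None, :])
        out50 = notch_filter(s50).data[0, 0, 200:-200]
        out40 = notch_filter(s40).data[0, 0, 200:-200]
        rms = lambda x: np.sqrt((x ** 2).mean())
        assert rms(out50) <= 0.1 * rms(self._sine(50.0)[200:-200])
        assert rms(out40) >= 0.94 * rms(self._sine(40.0)[200:-200])

    def test_zero_phase_keeps_symmetry(self):
        # symmetric about the array's reversal center (N-1)/2
        pulse = np.exp(-0.5 * ((np.arange(2000) - 999.5) / 30.0) ** 2)
        for flt in (lambda d: filter_array(d, (49, 51), FS, "bandstop"),
                    lambda d: filter_array(d, (5, 60), FS, "bandpass")):
            out = flt(pulse)
            np.testing.assert_allclose(out, out[::-1], rtol=0,
                                        atol=1e-8 * np.abs(out).max())

    def test_bandpass_passband_and_stopband(self):
        rms = lambda x: np.sqrt((x ** 2).mean())
        s40 = self._sine(40.0)
        out40 = bandpass(make_epochs(s40[None, None, :]), 5, 60).data[0, 0]
        assert rms(out40[200:-200]) == pytest.approx(rms(s40[200:-200]), rel=0.02)
        s2 = self._sine(2.0)
        out2 = bandpass(make_epochs(s2[None, None, :]), 5, 60).data[0, 0]
        assert rms(out2[200:-200]) <= 0.1 * rms(s2[200:-200])

    def test_double_filtering_preserves_passband(self):
        s40 = self._sine(40.0)
        ep = bandpass(bandpass(make_epochs(s40[None, None, :]), 5, 60), 5, 60)
        rms = lambda x: np.sqrt((x ** 2).mean())
        assert rms(ep.data[0, 0, 200:-200]) == pytest.approx(rms(s40[200:-200]), rel=0.04)

    def test_invalid_bands(self):
        ep = make_epochs(np.zeros((1, 1, 2000)))
        with pytest.raises(ValueError):
            bandpass(ep, 60, 5)
        with pytest.raises(ValueError):
            notch_filter(ep, (240, 260))


class TestMuscleScreen:
    def test_infinite_threshold_empty(self):
        ep = make_epochs(np.random.default_rng(0).standard_normal((10, 3, 2000)))
        assert detect_muscle_trials(ep, z_threshold=np.inf) == set()

    def test_injected_burst_flagged(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((20, 4, 2000))
        burst = filter_array(rng.standard_normal(300), (110, 140), FS, "bandpass")
        data[7, :, 800:1100] += 10.0 * burst / burst.std()
        ep = make_epochs(data)
        assert detect_muscle_trials(ep) == {7}

    def test_false_positive_rate_low(self):
        # simulation oracle: homogeneous noise yields <= 5% flags over 20 seeds
        total, flagged = 0, 0
        for seed in range(20):
            data = np.random.default_rng(seed).standard_normal((30, 4, 2000))
            flagged += len(detect_muscle_trials(make_epochs(data)))
            total += 30
        assert flagged / total <= 0.05

    def test_nyquist_guard(self):
        ep = make_epochs(np.zeros((2, 2, 1000)), fs=250.0)
        with pytest.raises(ValueError, match="before resampling"):
            detect_muscle_trials(ep)


class TestVarianceScreen:
    def test_flat_channel_flagged(self):
        data = np.random.default_rng(0).standard_normal((10, 5, 2000))
        data[:, 2, :] = 0.0
        out = detect_variance_outliers(make_epochs(data))
        assert out["bad_channels"] == {"C02": "flat"}

    def test_scaled_trial_flagged(self):
        data = np.random.default_rng(1).standard_normal((20, 5, 2000))
        data[11] *= 20.0
        out = detect_variance_outliers(make_epochs(data))
        assert 11 in out["bad_trials"]

    def test_false_positive_rate_low(self):
        total, flagged = 0, 0
        for seed in range(20):
            data = np.random.default_rng(100 + seed).standard_normal((30, 5, 2000))
            out = detect_variance_outliers(make_epochs(data))
            flagged += len(out["bad_trials"])
            total += 30
        assert flagged / total <= 0.05


class TestIca:
    def _eeg_session(self, seed, blink_rate):
        cfg = modality_preset("EEG", n_channels=25, sampling_rate_hz=500.0, seed=seed,
                              blink_rate_per_min=blink_rate, muscle_rate_per_min=0.0,
                              n_trials_per_condition={"40Hz": 30, "20Hz": 0, "60Hz": 0})
        rec = simulate_session(cfg)
        ep = epoch(rec)
        return rec, notch_filter(rereference_average(ep))

    @staticmethod
    def _blink_ground_truth(rec):
        """Epoch-aligned time course of the injected blink train."""
        from assrkit.synthgen import _blink_template

        trace = np.zeros_like(rec.data[:1])
        tmpl = _blink_template(rec.sampling_rate_hz)
        for a in rec.artifact_log:
            if a["kind"] == "blink":
                s = a["sample_index"]
                trace[0, s:s + a["n_samples"]] += a["amplitude"] * tmpl
        truth_rec = ContinuousRecording(trace, rec.sampling_rate_hz,
                                        rec.channel_info[:1], rec.events)
        return epoch(truth_rec).data[:, 0, :].reshape(-1)

    def test_blink_components_removed(self):
        rec, ep = self._eeg_session(seed=21, blink_rate=12.0)
        blink_tc = self._blink_ground_truth(rec)
        clean, n_removed = ica_clean(ep, PreprocessParams(ica_n_components=15))
        assert n_removed >= 1

        blink_lf = filter_array(blink_tc, (1, 10), FS, "bandpass")

        def worst_corr(data):
            worst = 0.0
            for i, c in enumerate(ep.channel_info):
                if c.position_tag == "eog":
                    continue
                ch = filter_array(data[:, i, :], (1, 10), FS, "bandpass").reshape(-1)
                worst = max(worst, abs(np.corrcoef(ch, blink_lf)[0, 1]))
            return worst

        assert worst_corr(ep.data) > 0.25       # contamination present before
        assert worst_corr(clean.data) < 0.2     # and projected out after

    def test_artifact_free_data_mostly_untouched(self):
        removed = [ica_clean(self._eeg_session(seed=s, blink_rate=0.0)[1],
                             PreprocessParams(ica_n_components=15))[1]
                   for s in range(40, 46)]
        assert int(np.median(removed)) == 0
        assert max(removed) <= 1

    def test_min_channel_guard(self):
        ep = make_epochs(np.zeros((5, 6, 500)))
        with pytest.raises(ValueError, match="channels"):
            ica_clean(ep)


class TestFullChain:
    @pytest.fixture(scope="class")
    def session(self):
        cfg = modality_preset("EEG", n_channels=25, sampling_rate_hz=500.0, seed=17)
        return simulate_session(cfg), PreprocessParams(ica_n_components=15)

    def test_retention_and_report_consistency(self, session):
        rec, params = session
        ep, report = run_preprocessing(rec, params)
        assert ep.n_trials >= 95 - len(report.bad_trials)
        assert 100 - ep.n_trials == len([t for t in report.bad_trials])
        # rejection volume on a default session is modest (same order as a
        # typical real session: a handful to a few dozen trials)
        assert len(report.bad_trials) <= 35
        assert report.removed_component_count <= 8
        assert np.all(np.diff(ep.kept_trial_ids) > 0)
        assert set(ep.condition_labels) == {"40Hz"}
        assert ep.sampling_rate_hz == 500.0

    def test_injected_artifact_trials_are_reported(self, session):
        rec, params = session
        rng = np.random.default_rng(0)
        dirty = ContinuousRecording(rec.data.copy(), rec.sampling_rate_hz,
                                    rec.channel_info, rec.events, rec.participant_id)
        targets = [5, 40, 77]
        fs = rec.sampling_rate_hz
        ev40 = [e for e in rec.events if e.condition == "40Hz"]
        scale = np.std(rec.data)
        for tid_40 in targets:
            # index within the 40 Hz trials -> position in the full event list
            tid = rec.events.index(ev40[tid_40])
            s = rec.events[tid].sample_index
            dirty.data[:, s:s + 500] += 25.0 * scale * rng.standard_normal((rec.n_channels, 500))
            assert tid == tid_40 or True
        ep, report = run_preprocessing(dirty, params)
        ev_ids = [rec.events.index(ev40[t]) for t in targets]
        assert set(ev_ids) <= set(report.bad_trials)
        assert not (set(ev_ids) & set(ep.kept_trial_ids))

    def test_bitwise_determinism(self, session):
        rec, params = session
        a, _ = run_preprocessing(rec, params)
        b, _ = run_preprocessing(rec, params)
        np.testing.assert_array_equal(a.data, b.data)
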