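"""Spatial-filter contracts: subset selection, CCA weights vs a brute-force
oracle, virtual-channel projection, polarity correction, invariances."""
from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize

import assrkit as ak
from assrkit.containers import SpatialFilterSpec
from assrkit.preprocess import filter_array
from assrkit.spatialfilter import (apply_filter, build_extrema_template,
                                   fit_cca_filter, fix_polarity,
                                   select_channel_subset)
from assrkit.synthgen import modality_preset, simulate_session

from conftest import FS, make_epochs


def windowed_sine(freq=40.0, n=2000, fs=FS):
    t = (np.arange(n) - int(fs)) / fs
    return np.sin(2 * np.pi * freq * t) * ((t >= 0) & (t < 1))


def toy_epochs(pattern, n_trials=25, noise_sd=0.5, seed=0, amp=1.0):
    rng = np.random.default_rng(seed)
    sig = amp * windowed_sine()
    data = np.asarray(pattern)[None, :, None] * sig[None, None, :]
    data = data + noise_sd * rng.standard_normal((n_trials, len(pattern), sig.size))
    return make_epochs(data)


class TestSubsetSelection:
    def test_squid_temporal_tags(self):
        cfg = modality_preset("SQUID", n_channels=40, sampling_rate_hz=500.0, seed=0,
                              n_trials_per_condition={"40Hz": 3, "20Hz": 0, "60Hz": 0})
        ep = ak.epoch(simulate_session(cfg))
        sub = select_channel_subset(ep, 10)
        tags = [c.position_tag for c in sub.channel_info]
        assert len(sub.channel_info) == 10
        assert tags.count("temporal_left") == 5 and tags.count("temporal_right") == 5

    def test_opm_keeps_both_axes(self):
        cfg = modality_preset("OPM", n_channels=24, sampling_rate_hz=500.0, seed=0,
                              n_trials_per_condition={"40Hz": 3, "20Hz": 0, "60Hz": 0})
        ep = ak.epoch(simulate_session(cfg))
        sub = select_channel_subset(ep, 10)
        assert len(sub.channel_info) == 20              # 10 sites x 2 axes
        assert len({c.site for c in sub.channel_info}) == 10
        assert {c.axis for c in sub.channel_info} == {"rad", "tan"}

    def test_eeg_topography_selects_frontocentral(self):
        tags = ["frontocentral"] * 6 + ["parietal"] * 6 + ["eog"]
        amp = np.array([5, 5, 5, 5, 5, 5, 1, 1, 1, 1, 1, 1, 9.0])  # EOG large but excluded
        ep = make_epochs(np.zeros((2, 13, 100)), modality="EEG", tags=tags)
        sub = select_channel_subset(ep, 6, amp)
        assert {c.position_tag for c in sub.channel_info} == {"frontocentral"}

    def test_too_many_requested(self):
        ep = make_epochs(np.zeros((2, 5, 100)), modality="EEG",
                         tags=["frontal"] * 4 + ["eog"])
        with pytest.raises(ValueError):
            select_channel_subset(ep, 10, np.arange(5.0))


class TestCcaFit:
    def test_single_channel_degenerate(self):
        ep = toy_epochs([1.0])
        spec = fit_cca_filter(ep)
        np.testing.assert_allclose(spec.weights, [1.0])

    def test_noisy_channel_downweighted(self):
        # channel 1 carries the signal at SNR 10, channel 2 independent noise
        ep = toy_epochs([1.0, 0.0], noise_sd=0.1, seed=2)
        w = fit_cca_filter(ep).weights
        assert abs(w[0]) / abs(w[1]) > 5

    def test_matches_bruteforce_covariance_maximizer(self):
        # dense-oracle: maximize canonical correlation over the unit sphere
        ep = toy_epochs([1.0, -0.6, 0.25], noise_sd=0.8, seed=7, n_trials=30)
        spec = fit_cca_filter(ep)

        flt = filter_array(ep.data, (39, 41), FS, "bandpass")
        sel = (ep.time_axis_s >= 0.25) & (ep.time_axis_s <= 1.0)
        tr = flt[:, :, sel]
        avg = tr.mean(axis=0)
        X = tr.transpose(1, 0, 2).reshape(3, -1)
        Y = np.tile(avg, (1, tr.shape[0]))
        X = X - X.mean(1, keepdims=True)
        Y = Y - Y.mean(1, keepdims=True)
        Cyy = Y @ Y.T

        def negrho2(w):
            w = w / np.linalg.norm(w)
            x = w @ X
            b = Y @ x
            return -(b @ np.linalg.solve(Cyy, b)) / (x @ x)

        rng = np.random.default_rng(0)
        best = min((minimize(negrho2, rng.standard_normal(3), method="Nelder-Mead",
                             options=dict(xatol=1e-10, fatol=1e-14, maxiter=5000))
                    for _ in range(5)), key=lambda r: r.fun)
        w_bf = best.x / np.linalg.norm(best.x)
        cos = abs(np.dot(spec.weights, w_bf))
        assert cos > 0.999
        assert spec.canonical_correlation_value == pytest.approx(np.sqrt(-best.fun), abs=1e-3)

    def test_empty_fit_window(self):
        ep = toy_epochs([1.0, 0.5])
        with pytest.raises(ValueError, match="window"):
            fit_cca_filter(ep, fit_window_s=(5.0, 6.0))


class TestApplyFilter:
    def test_unit_vector_projection(self):
        data = np.random.default_rng(0).standard_normal((4, 3, 100))
        ep = make_epochs(data)
        spec = SpatialFilterSpec(weights=np.array([0.0, 1.0, 0.0]))
        virt = apply_filter(ep, spec)
        np.testing.assert_allclose(virt.data, data[:, 1, :])

    def test_zero_data_and_weight_scaling(self):
        ep = make_epochs(np.zeros((2, 3, 50)))
        spec = SpatialFilterSpec(weights=np.ones(3))
        assert np.all(apply_filter(ep, spec).data == 0)
        data = np.random.default_rng(1).standard_normal((2, 3, 50))
        ep = make_epochs(data)
        v1 = apply_filter(ep, SpatialFilterSpec(weights=np.array([1.0, 2.0, -1.0])))
        v3 = apply_filter(ep, SpatialFilterSpec(weights=3 * np.array([1.0, 2.0, -1.0])))
        np.testing.assert_allclose(v3.data, 3 * v1.data)

    def test_dimension_mismatch(self):
        ep = make_epochs(np.zeros((2, 3, 50)))
        with pytest.raises(ValueError):
            apply_filter(ep, SpatialFilterSpec(weights=np.ones(4)))


class TestExtremaTemplate:
    def test_sine_extrema_counts(self):
        fs = 500.0
        t = np.arange(0, 1.2, 1 / fs)
        x = np.sin(2 * np.pi * 40 * t)
        ext = build_extrema_template(x, t, window_s=(0.25, 1.0))
        kinds = [e["type"] for e in ext]
        assert kinds.count("max") == 30 and kinds.count("min") == 30

    def test_single_cycle(self):
        fs = 2000.0
        t = np.arange(0, 0.025, 1 / fs)
        x = np.sin(2 * np.pi * 40 * t)
        ext = build_extrema_template(x, t, window_s=(0.0, 0.025))
        kinds = [e["type"] for e in ext]
        assert kinds.count("max") == 1 and kinds.count("min") == 1

    def test_flat_input_rejected(self):
        with pytest.raises(ValueError):
            build_extrema_template(np.ones(100), np.linspace(0, 1, 100))


class TestPolarity:
    def _virtual_and_template(self):
        sig = windowed_sine()
        data = np.tile(sig, (5, 1)) + 0.01 * np.random.default_rng(0).standard_normal((5, 2000))
        ep = make_epochs(data[:, None, :])
        virt = apply_filter(ep, SpatialFilterSpec(weights=np.array([1.0])))
        tmpl = build_extrema_template(sig, virt.time_axis_s)
        return virt, tmpl

    def test_correct_polarity_unchanged(self):
        virt, tmpl = self._virtual_and_template()
        out = fix_polarity(virt, tmpl)
        np.testing.assert_array_equal(out.data, virt.data)

    def test_involution_and_idempotence(self):
        virt, tmpl = self._virtual_and_template()
        flipped = ak.VirtualChannelEpochs(-virt.data, virt.time_axis_s,
                                          virt.sampling_rate_hz, virt.kept_trial_ids)
        back = fix_polarity(flipped, tmpl)
        np.testing.assert_array_equal(back.data, virt.data)
        twice = fix_polarity(back, tmpl)
        np.testing.assert_array_equal(twice.data, back.data)

    def test_template_index_out_of_range(self):
        virt, _ = self._virtual_and_template()
        with pytest.raises(ValueError):
            fix_polarity(virt, [{"sample_index": 99999, "type": "max"},
                                {"sample_index": 0, "type": "min"}])


class TestInvariances:
    def test_sign_invariance_of_corrected_virtual(self):
        ep = toy_epochs([1.0, -0.6, 0.25], seed=5)
        tmpl = build_extrema_template(windowed_sine(), ep.time_axis_s)
        v1 = fix_polarity(apply_filter(ep, fit_cca_filter(ep)), tmpl)
        neg = ep.copy_with(data=-ep.data)
        v2 = fix_polarity(apply_filter(neg, fit_cca_filter(neg)), tmpl)
        np.testing.assert_allclose(v1.data, v2.data, atol=1e-10 * np.abs(v1.data).max())

    def test_scale_invariance_of_metrics(self):
        ep = toy_epochs([1.0, -0.6], seed=6)
        spec = fit_cca_filter(ep)
        v1 = apply_filter(ep, spec)
        scaled = ep.copy_with(data=3.7 * ep.data)
        spec2 = fit_cca_filter(scaled)
        v2 = apply_filter(scaled, spec2)
        s1 = ak.snr_from_power(ak.power_of_average(v1)).snr
        s2 = ak.snr_from_power(ak.power_of_average(v2)).snr
        assert s1 == pytest.approx(s2, rel=1e-9)
        r1 = ak.itpc_ratio(ak.itpc_map(v1)).snr
        r2 = ak.itpc_ratio(ak.itpc_map(v2)).snr
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_virtual_snr_non_inferior_to_best_channel(self):
        # the motivation for the filter: pooling channels should not lose SNR
        wins = 0
        for seed in range(10):
            cfg = modality_preset("OPM", n_channels=8, sampling_rate_hz=500.0,
                                  seed=seed, blink_rate_per_min=0.0,
                                  muscle_rate_per_min=0.0,
                                  n_trials_per_condition={"40Hz": 25, "20Hz": 0, "60Hz": 0})
            ep = ak.epoch(simulate_session(cfg))
            virt = apply_filter(ep, fit_cca_filter(ep))
            snr_virt = ak.snr_from_power(ak.power_of_average(virt)).snr
            best = 0.0
            for c in range(ep.n_channels):
                v = ak.VirtualChannelEpochs(ep.data[:, c, :], ep.time_axis_s,
                                            ep.sampling_rate_hz, ep.kept_trial_ids)
                best = max(best, ak.snr_from_power(ak.power_of_average(v)).snr)
            if snr_virt >= 0.95 * best:
                wins += 1
        assert wins >= 9
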