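import numpy as np
import pandas as pd
import pytest

from meaburst import synthetic as syn
from meaburst.waveforms import waveform_features


class TestPresets:
    def test_sham_preset_is_identity(self, presets):
        sham = presets["sham"]
        assert sham.burst_rate_scale == sham.background_rate_scale == 1.0
        assert sham.burst_duration_scale == sham.intra_burst_rate_scale == 1.0
        assert sham.jitter_scale == 1.0 and not sham.rebound

    def test_rebound_only_in_muscimol_like_preset(self, presets):
        assert presets["mu"].rebound and not presets["rf"].rebound

    def test_muscimol_like_desynchronizes_more_than_rf_like(self, presets):
        assert presets["mu"].jitter_scale > presets["rf"].jitter_scale

    def test_invalid_parameters_rejected(self):
        with pytest.raises(syn.ProtocolError):
            syn.EffectPreset(name="bad", burst_rate_scale=0.0)
        with pytest.raises(syn.ProtocolError):
            syn.EffectPreset(name="bad", rebound_duration=200.0)
        with pytest.raises(syn.ProtocolError):
            syn.ProtocolSpec(baseline_duration=0.0)
        with pytest.raises(syn.ProtocolError):
            syn.ProtocolSpec(n_channels=0)


class TestGenerateSpikeTrains:
    def test_sham_exposure_rate_matches_baseline(self, sham_culture, small_protocol):
        trains, _ = sham_culture
        t1, t2 = small_protocol.phase_boundaries
        pooled = np.concatenate(list(trains.times.values()))
        base_rate = np.sum(pooled < t1) / t1
        exp_rate = np.sum((pooled >= t1) & (pooled < t2)) / (t2 - t1)
        assert exp_rate == pytest.approx(base_rate, rel=0.05)

    def test_full_participation_no_isolated_gives_network_only(self, small_protocol):
        model = syn.NetworkActivityModel(burst_participation=1.0,
                                         isolated_burst_fraction=0.0)
        _, truth = syn.generate_spike_trains(
            small_protocol, model, syn.builtin_presets()["sham"], seed=3)
        assert truth["network_flag"].all()
        # every network event recruits every channel (overlap-merging may
        # fuse a couple of bursts per channel)
        per_channel = truth.groupby("channel").size()
        assert per_channel.max() - per_channel.min() <= 3

    def test_mean_burst_count_matches_monte_carlo_expectation(self):
        # 12 network events/min recruiting 80 % of channels over a 30 min
        # baseline: expected per-channel ground-truth burst count is
        # 12 * 30 * 0.8 = 288; Monte-Carlo mean over seeds/channels must sit
        # within sampling error of that.
        protocol = syn.ProtocolSpec(baseline_duration=1800.0, exposure_duration=60.0,
                                    post_duration=60.0, n_channels=10)
        model = syn.NetworkActivityModel(network_burst_rate=12.0,
                                         burst_participation=0.8,
                                         isolated_burst_fraction=0.0)
        counts = []
        for seed in range(10):
            _, truth = syn.generate_spike_trains(
                protocol, model, syn.builtin_presets()["sham"], seed=seed)
            baseline = truth[truth["start_s"] < 1800.0]
            counts.extend(baseline.groupby("channel").size().to_numpy())
        assert np.mean(counts) == pytest.approx(288.0, abs=6.0)

    def test_network_burst_fraction_in_study_range(self, sham_culture):
        _, truth = sham_culture
        frac = truth["network_flag"].mean()
        assert 0.6 <= frac <= 0.8

    def test_truth_intervals_sorted_and_inside_record(self, sham_culture, small_protocol):
        trains, truth = sham_culture
        assert (truth["end_s"] > truth["start_s"]).all()
        assert truth["start_s"].min() >= 0.0
        assert truth["end_s"].max() <= small_protocol.duration
        for ch in trains.channels:
            t = trains.times[ch]
            assert np.all(np.diff(t) > 0)
            assert t[0] >= 0 and t[-1] < small_protocol.duration

    def test_same_seed_reproduces_identical_output(self, small_protocol, model, presets):
        a_trains, a_truth = syn.generate_spike_trains(small_protocol, model,
                                                      presets["mu"], seed=11)
        b_trains, b_truth = syn.generate_spike_trains(small_protocol, model,
                                                      presets["mu"], seed=11)
        for ch in a_trains.channels:
            np.testing.assert_array_equal(a_trains.times[ch], b_trains.times[ch])
        pd.testing.assert_frame_equal(a_truth, b_truth)

    def test_muscimol_like_rebound_elevates_first_post_minute(self, small_protocol,
                                                              model, presets):
        trains, _ = syn.generate_spike_trains(small_protocol, model, presets["mu"],
                                              seed=5)
        t1, t2 = small_protocol.phase_boundaries
        pooled = np.concatenate(list(trains.times.values()))
        last_exposure = np.sum((pooled >= t2 - 60) & (pooled < t2))
        first_post = np.sum((pooled >= t2) & (pooled < t2 + 60))
        assert first_post > last_exposure


class TestRenderRawRecording:
    def test_empty_trains_render_pure_noise(self, rng):
        protocol = syn.ProtocolSpec(baseline_duration=30.0, exposure_duration=15.0,
                                    post_duration=15.0, n_channels=1)
        from meaburst.io import SpikeTrainSet

        trains = SpikeTrainSet({0: np.empty(0)}, duration=protocol.duration,
                               phase_boundaries=protocol.phase_boundaries)
        bank = syn.WaveformTemplateBank.default([0], noise_sd=3.0)
        rec, _ = syn.render_raw_recording(trains, bank, protocol,
                                          syn.builtin_presets()["sham"], seed=2)
        assert np.std(rec.voltages[0]) == pytest.approx(3.0, rel=0.02)

    def test_single_spike_noise_free_equals_template(self):
        protocol = syn.ProtocolSpec(baseline_duration=1.0, exposure_duration=0.5,
                                    post_duration=0.5, n_channels=1)
        from meaburst.io import SpikeTrainSet

        trains = SpikeTrainSet({0: np.array([0.5])}, duration=protocol.duration,
                               phase_boundaries=protocol.phase_boundaries)
        tmpl = syn.WaveformTemplate(60.0, 0.35, 18.0, abundance=1.0)
        bank = syn.WaveformTemplateBank({0: [tmpl]}, noise_sd=0.0)
        rec, _ = syn.render_raw_recording(trains, bank, protocol,
                                          syn.builtin_presets()["sham"], seed=2)
        c = int(round(0.5 * protocol.sampling_rate))
        np.testing.assert_allclose(rec.voltages[0][c - 8:c + 32],
                                   tmpl.render(protocol.sampling_rate), atol=1e-12)
        assert np.all(rec.voltages[0][:c - 8] == 0)

    def test_halfwidth_scale_narrows_rendered_exposure_template(self):
        protocol = syn.ProtocolSpec(baseline_duration=1.0, exposure_duration=1.0,
                                    post_duration=0.5, n_channels=1)
        from meaburst.io import SpikeTrainSet

        trains = SpikeTrainSet({0: np.array([0.5, 1.5])}, duration=protocol.duration,
                               phase_boundaries=protocol.phase_boundaries)
        tmpl = syn.WaveformTemplate(60.0, 0.35, 18.0, abundance=1.0)
        bank = syn.WaveformTemplateBank({0: [tmpl]}, noise_sd=0.0)
        preset = syn.EffectPreset(name="narrow", ap_halfwidth_scale=0.9)
        rec, _ = syn.render_raw_recording(trains, bank, protocol, preset, seed=2)
        fs = protocol.sampling_rate
        base = rec.voltages[0][int(0.5 * fs) - 8:int(0.5 * fs) + 32]
        expo = rec.voltages[0][int(1.5 * fs) - 8:int(1.5 * fs) + 32]
        f_base = waveform_features(base, fs).fwhm_ms
        f_expo = waveform_features(expo, fs).fwhm_ms
        assert f_expo / f_base == pytest.approx(0.9, abs=0.03)

    def test_template_longer_than_snippet_window_rejected(self):
        with pytest.raises(syn.ProtocolError):
            syn.WaveformTemplate(60.0).render(10_000.0, n_samples=50)


class TestDosePanels:
    def test_panel_replicate_counts_match_study_layout(self):
        mu = syn.agonist_dose_panel(seed=1)
        assert len(mu) == 14
        assert mu.groupby("dose").size().tolist() == list(syn.MU_DOSE_REPLICATES)
        sar = syn.sar_dose_panel(seed=1)
        assert sar.groupby("dose").size().tolist() == list(syn.SAR_DOSE_REPLICATES)

    def test_panels_descend_with_dose(self):
        mu = syn.agonist_dose_panel(seed=2, noise_sd=0.0)
        means = mu.groupby("dose")["r_mbr"].mean()
        assert means.iloc[0] > 0.95
        assert means.iloc[-1] < 0.2
        assert (np.diff(means.to_numpy()) < 0).all()
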