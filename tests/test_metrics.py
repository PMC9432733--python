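import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from meaburst.bursts import detect_bursts_trainset
from meaburst.io import ExperimentPhase, SpikeTrainSet
from meaburst.metrics import (PipelineError, active_channel_filter, compute_panel,
                              cv_sync, initial_inhibitory_rate, norm_rmse,
                              normalize, pooled_panel, pooled_ratio,
                              postinhibitory_rebound, time_course)


def _burst_table(rows):
    return pd.DataFrame(rows, columns=["channel", "start_s", "end_s",
                                       "n_spikes", "network_flag"])


def _trains(times: dict, duration=900.0, bounds=(300.0, 600.0)):
    return SpikeTrainSet({k: np.asarray(v, float) for k, v in times.items()},
                         duration=duration, phase_boundaries=bounds)


class TestComputePanel:
    def test_fifteen_bursts_in_fifteen_minutes_is_one_per_minute(self):
        starts = np.arange(15) * 60.0 + 5.0
        table = _burst_table([(0, s, s + 0.5, 10, False) for s in starts])
        spikes = np.sort(np.concatenate([np.linspace(s, s + 0.5, 10) for s in starts]))
        trains = _trains({0: spikes}, duration=1800.0, bounds=(900.0, 1350.0))
        panel = compute_panel(trains, table, ExperimentPhase.BASELINE)
        assert panel.loc[0, "MBR"] == pytest.approx(1.0, rel=1e-6)

    def test_intra_burst_rate_from_counts_and_duration(self):
        # bursts of 0.2 s holding 30 spikes each -> IBSR = 150 spikes/s
        rows, spikes = [], []
        for s in (10.0, 20.0, 30.0):
            rows.append((0, s, s + 0.2, 30, False))
            spikes.append(np.linspace(s, s + 0.2, 30))
        trains = _trains({0: np.sort(np.concatenate(spikes))}, duration=120.0,
                         bounds=(60.0, 90.0))
        panel = compute_panel(trains, _burst_table(rows), ExperimentPhase.BASELINE)
        assert panel.loc[0, "IBSR"] == pytest.approx(150.0)
        assert panel.loc[0, "BD"] == pytest.approx(0.2)

    def test_two_channel_toy_panel_matches_hand_calculation(self):
        # channel 0: two 10-spike bursts (ISI 50 ms) plus two lone spikes in
        # a 60 s window; channel 1: three 5-spike bursts (ISI 20 ms)
        b0 = [10.0 + 0.05 * i for i in range(10)]
        b1 = [30.0 + 0.05 * i for i in range(10)]
        ch0 = np.sort(np.array(b0 + b1 + [5.0, 50.0]))
        c0 = [15.0 + 0.02 * i for i in range(5)]
        c1 = [25.0 + 0.02 * i for i in range(5)]
        c2 = [45.0 + 0.02 * i for i in range(5)]
        ch1 = np.sort(np.array(c0 + c1 + c2))
        trains = _trains({0: ch0, 1: ch1}, duration=120.0, bounds=(60.0, 90.0))
        table = detect_bursts_trainset(trains)
        panel = compute_panel(trains, table, ExperimentPhase.BASELINE)
        # hand enumeration, channel 0
        assert panel.loc[0, "MBR"] == pytest.approx(2 / 1.0)           # 2 bursts/min
        assert panel.loc[0, "BD"] == pytest.approx(0.45)
        assert panel.loc[0, "IBI"] == pytest.approx(30.0 - 10.45)
        assert panel.loc[0, "IBSR"] == pytest.approx(20 / 0.9)
        assert panel.loc[0, "MSR"] == pytest.approx(2 / (60.0 - 0.9), rel=1e-3)
        # hand enumeration, channel 1
        assert panel.loc[1, "MBR"] == pytest.approx(3.0)
        assert panel.loc[1, "BD"] == pytest.approx(0.08)
        assert panel.loc[1, "IBI"] == pytest.approx(((25 - 15.08) + (45 - 25.08)) / 2)
        assert panel.loc[1, "IBSR"] == pytest.approx(15 / 0.24)
        # pooled panel is the unweighted channel mean
        pooled = pooled_panel(panel)
        assert pooled["MBR"] == pytest.approx((2 + 3) / 2)

    def test_spike_count_conservation_in_and_out_of_bursts(self, sham_culture):
        trains, _ = sham_culture
        table = detect_bursts_trainset(trains)
        for phase in ExperimentPhase:
            t0, t1 = trains.phase_window(phase)
            panel = compute_panel(trains, table, phase)
            for ch in trains.channels:
                t = trains.times[ch]
                total = np.sum((t >= t0) & (t < t1))
                b = table[(table["channel"] == ch) & (table["start_s"] >= t0)
                          & (table["start_s"] < t1)]
                burst_time = float((np.minimum(b["end_s"], t1) - b["start_s"]).sum())
                in_spk = panel.loc[ch, "IBSR"] * burst_time if burst_time else 0.0
                out_spk = panel.loc[ch, "MSR"] * ((t1 - t0) - burst_time)
                assert in_spk + out_spk == pytest.approx(total, abs=1e-6)


class TestNormalization:
    def test_identical_phases_normalize_to_one(self):
        panel = pd.DataFrame({"MBR": [2.0, 3.0], "MSR": [1.0, 1.5]})
        out = normalize(panel, panel)
        assert np.allclose(out.to_numpy(), 1.0)
        assert np.allclose(pooled_ratio(panel, panel).to_numpy(), 1.0)

    def test_halved_rate_gives_half(self):
        base = pd.DataFrame({"MBR": [2.0]})
        expo = pd.DataFrame({"MBR": [1.0]})
        assert normalize(expo, base).loc[0, "MBR"] == pytest.approx(0.5)

    def test_zero_baseline_flagged_undefined(self):
        base = pd.DataFrame({"MBR": [0.0]})
        expo = pd.DataFrame({"MBR": [1.0]})
        assert np.isnan(normalize(expo, base).loc[0, "MBR"])


class TestCvSync:
    def test_identical_bursts_give_zero_cv(self):
        rows = []
        for ch in range(3):
            for k in range(5):
                rows.append((ch, 10.0 * k, 10.0 * k + 0.5, 25, False))
        trains = _trains({ch: [1.0] for ch in range(3)}, duration=120.0,
                         bounds=(60.0, 90.0))
        assert cv_sync(_burst_table(rows), trains, ExperimentPhase.BASELINE,
                       "BD") == pytest.approx(0.0)
        assert cv_sync(_burst_table(rows), trains, ExperimentPhase.BASELINE,
                       "IBI") == pytest.approx(0.0)

    def test_direct_arithmetic_example(self):
        # channel 0 inter-burst gaps {0.8, 1.0, 1.2} (sd 0.2), channel 1 gaps
        # {0.6, 1.0, 1.4} (sd 0.4); pooled mean 1.0 -> CV = 30 %
        rows = []
        for ch, gaps in ((0, [0.8, 1.0, 1.2]), (1, [0.6, 1.0, 1.4])):
            t = 1.0
            rows.append((ch, t, t + 0.1, 5, False))
            for g in gaps:
                start = t + 0.1 + g
                rows.append((ch, start, start + 0.1, 5, False))
                t = start
        trains = _trains({0: [1.0], 1: [1.0]}, duration=120.0, bounds=(60.0, 90.0))
        cv = cv_sync(_burst_table(rows), trains, ExperimentPhase.BASELINE, "IBI")
        assert cv == pytest.approx(30.0)

    def test_muscimol_like_raises_cv_ibi_over_sham(self, small_protocol, model, presets):
        from meaburst.pipeline import simulate_arm

        sham = simulate_arm(presets["sham"], 3, seed=21, protocol=small_protocol)
        mu = simulate_arm(presets["mu"], 3, seed=21, arm_index=1, protocol=small_protocol)
        assert mu["R_cv_IBI"].median() > sham["R_cv_IBI"].median()


class TestNormRmse:
    def test_worked_examples(self):
        assert norm_rmse([0.5, 1.5], 1.0) == pytest.approx(0.5)
        assert norm_rmse([0.8, 1.2], 1.0) == pytest.approx(0.2)
        assert norm_rmse([1.0, 1.0, 1.0]) == 0.0

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, c):
        y = np.array([0.4, 0.9, 1.3, 1.7])
        assert norm_rmse(c * y, c * float(np.mean(y))) == pytest.approx(
            norm_rmse(y, float(np.mean(y))), rel=1e-9)

    def test_zero_mea_value_undefined(self):
        assert np.isnan(norm_rmse([0.0, 0.0]))


class TestTimeCourse:
    def test_homogeneous_train_is_flat_at_one(self):
        t = np.arange(0, 900, 0.5)
        tc = time_course(t, 900.0, (300.0, 600.0), bin_width=60.0)
        assert np.allclose(tc.normalized, 1.0)
        assert initial_inhibitory_rate(tc) == pytest.approx(0.0, abs=1e-9)
        assert postinhibitory_rebound(tc) == pytest.approx(1.0)

    def test_halved_rate_steps_down(self):
        t = np.concatenate([np.arange(0, 450, 0.5), np.arange(450, 900, 1.0)])
        tc = time_course(t, 900.0, (300.0, 600.0), bin_width=60.0)
        assert np.allclose(tc.normalized[:5], 1.0)
        assert np.allclose(tc.normalized[8:], 0.5)

    def test_initial_inhibitory_rate_closed_form(self):
        # normalized course dropping linearly 1 -> 0.5 over the first five
        # exposure minutes: OLS slope is -0.125 / min
        tc = time_course(np.arange(0, 900, 0.5), 900.0, (300.0, 600.0), 60.0)
        vals = tc.normalized.copy()
        vals[tc.phase_bins(ExperimentPhase.EXPOSURE)[:5]] = np.linspace(1.0, 0.5, 5)
        tc.normalized = vals
        assert initial_inhibitory_rate(tc) == pytest.approx(-0.125)

    def test_bins_tile_record_exactly(self):
        tc = time_course(np.arange(0, 900, 0.5), 900.0, (300.0, 600.0), 60.0)
        assert tc.bin_edges[0] == 0.0 and tc.bin_edges[-1] == 900.0
        assert np.all(np.diff(tc.bin_edges) > 0)


class TestActiveChannels:
    def test_silent_and_burstless_channels_inactive(self):
        spikes = np.arange(10, 290, 0.02)
        table = _burst_table([(0, 10.0 + k, 10.0 + k + 0.3, 16, False)
                              for k in range(0, 280, 10)])
        trains = _trains({0: spikes, 1: np.array([100.0]),
                          2: np.arange(10.0, 290.0, 1.0)},
                         duration=900.0, bounds=(300.0, 600.0))
        active = active_channel_filter(trains, table)
        assert active == [0]  # 1 is nearly silent, 2 spikes but never bursts

    def test_all_inactive_raises(self):
        trains = _trains({0: np.array([1.0])}, duration=900.0, bounds=(300.0, 600.0))
        with pytest.raises(PipelineError):
            active_channel_filter(trains, _burst_table([]))
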