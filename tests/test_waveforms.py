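import numpy as np
import pytest

from meaburst.synthetic import WaveformTemplate
from meaburst.waveforms import (FEATURE_NAMES, FeatureError, classify_clusters,
                                feature_change, phase_plot, sort_spikes,
                                waveform_features)

FS = 10_000.0


def _gaussian_trough(sigma_ms: float, depth: float = 10.0) -> np.ndarray:
    t = (np.arange(40) - 8) / FS * 1e3
    return -depth * np.exp(-0.5 * (t / sigma_ms) ** 2)


def _snippets_from(template: np.ndarray, n: int, noise_sd: float,
                   rng: np.random.Generator) -> np.ndarray:
    return template[None, :] + rng.normal(0, noise_sd, size=(n, template.size))


class TestWaveformFeatures:
    def test_triangular_trough_fwhm_is_exact(self):
        # symmetric triangle of depth 10 whose half-depth crossings are
        # exactly 0.4 ms apart (4 samples down, 4 up -> half level at
        # sample offset +/- 2)
        w = np.zeros(40)
        for k in range(1, 5):
            w[8 - 4 + k] = -10.0 * k / 4.0
            w[8 + 4 - k] = -10.0 * k / 4.0
        w[8] = -10.0
        f = waveform_features(w, FS)
        assert f.fwhm_ms == pytest.approx(0.4)
        assert f.anti_peak == pytest.approx(10.0)

    def test_gaussian_trough_fwhm_matches_closed_form(self):
        sigma = 0.2
        f = waveform_features(_gaussian_trough(sigma), FS)
        assert f.fwhm_ms == pytest.approx(2.3548 * sigma, abs=0.1)  # one sample

    def test_scaling_doubles_amplitudes_and_slopes_not_width(self):
        w = WaveformTemplate(60.0, 0.35, 18.0).render(FS)
        f1 = waveform_features(w, FS)
        f2 = waveform_features(2 * w, FS)
        assert f2.anti_peak == pytest.approx(2 * f1.anti_peak)
        assert f2.peak == pytest.approx(2 * f1.peak)
        assert f2.max_rising_slope == pytest.approx(2 * f1.max_rising_slope)
        assert f2.max_falling_slope == pytest.approx(2 * f1.max_falling_slope)
        assert f2.fwhm_ms == pytest.approx(f1.fwhm_ms)

    def test_no_trough_is_a_feature_error(self):
        with pytest.raises(FeatureError):
            waveform_features(np.ones(40), FS)


class TestClassifyClusters:
    def test_fraction_rule(self):
        labels = np.array([0] * 70 + [1] * 20 + [2] * 10)
        assert classify_clusters(labels) == {0: "MAJ", 1: "AUX", 2: "MIN"}

    def test_single_cluster_is_major(self):
        assert classify_clusters(np.zeros(30, dtype=int)) == {0: "MAJ"}

    def test_tie_breaks_toward_lower_index(self):
        labels = np.array([0] * 50 + [1] * 50)
        assert classify_clusters(labels) == {0: "MAJ", 1: "AUX"}

    def test_unsorted_spikes_ignored(self):
        labels = np.array([-1] * 100 + [0] * 10)
        assert classify_clusters(labels) == {0: "MAJ"}


class TestSortSpikes:
    def test_single_template_yields_one_well_sorted_cluster(self, rng):
        tmpl = WaveformTemplate(60.0, 0.35, 18.0).render(FS)
        snips = _snippets_from(tmpl, 300, 3.0, rng)
        labels = sort_spikes(snips, seed=0)
        sorted_lbl = labels[labels >= 0]
        assert np.mean(labels >= 0) >= 0.95
        assert np.unique(sorted_lbl).size == 1

    def test_two_separated_templates_recovered(self, rng):
        a = WaveformTemplate(60.0, 0.35, 18.0).render(FS)
        b = WaveformTemplate(35.0, 0.30, 10.0).render(FS)  # 25 uV apart >> 3 sd
        snips = np.vstack([_snippets_from(a, 200, 3.0, rng),
                           _snippets_from(b, 150, 3.0, rng)])
        truth = np.array([0] * 200 + [1] * 150)
        labels = sort_spikes(snips, seed=0)
        ok = labels >= 0
        # map each found cluster to its majority truth class
        agreement = 0
        for k in np.unique(labels[ok]):
            sel = labels == k
            majority = np.bincount(truth[sel]).argmax()
            agreement += np.sum(truth[sel] == majority)
        assert agreement / np.sum(ok) >= 0.9
        assert np.unique(labels[ok]).size == 2

    def test_pure_noise_finds_no_spurious_structure(self, rng):
        snips = rng.normal(0, 3.0, size=(200, 40))
        labels = sort_spikes(snips, seed=0)
        assert np.unique(labels[labels >= 0]).size == 1

    def test_too_few_snippets_skipped(self, rng):
        snips = rng.normal(0, 3.0, size=(10, 40))
        assert np.all(sort_spikes(snips, seed=0) == -1)

    def test_permutation_invariance_up_to_relabeling(self, rng):
        a = WaveformTemplate(60.0, 0.35, 18.0).render(FS)
        b = WaveformTemplate(35.0, 0.30, 10.0).render(FS)
        snips = np.vstack([_snippets_from(a, 100, 3.0, rng),
                           _snippets_from(b, 100, 3.0, rng)])
        perm = rng.permutation(snips.shape[0])
        l0 = sort_spikes(snips, seed=0)
        l1 = sort_spikes(snips[perm], seed=0)
        # compare partitions, not label names
        def partition(labels):
            return {tuple(sorted(np.flatnonzero(labels == k)))
                    for k in np.unique(labels) if k >= 0}
        inv = np.empty_like(perm)
        inv[perm] = np.arange(perm.size)
        assert partition(l0) == partition(l1[inv])


class TestFeatureChange:
    def test_identical_phases_give_unit_ratios(self):
        w = WaveformTemplate(60.0, 0.35, 18.0).render(FS)
        f = waveform_features(w, FS)
        per_unit, mea = feature_change({0: f}, {0: f}, {0: "MAJ"})
        assert np.allclose(per_unit[0], 1.0)
        assert np.allclose(mea, 1.0)

    def test_rendered_narrowing_shows_in_ratios(self):
        tmpl = WaveformTemplate(60.0, 0.35, 18.0)
        f_base = waveform_features(tmpl.render(FS), FS)
        f_expo = waveform_features(tmpl.render(FS, width_scale=0.9), FS)
        _, mea = feature_change({0: f_expo}, {0: f_base}, {0: "MAJ"})
        ratios = dict(zip(FEATURE_NAMES, mea))
        assert ratios["fwhm_ms"] == pytest.approx(0.9, abs=0.05)
        assert ratios["anti_peak"] == pytest.approx(1.0, abs=0.02)
        assert ratios["max_rising_slope"] > 1.0
        assert ratios["max_falling_slope"] > 1.0

    def test_unit_missing_in_one_phase_excluded(self):
        w = WaveformTemplate(60.0, 0.35, 18.0).render(FS)
        f = waveform_features(w, FS)
        per_unit, mea = feature_change({0: f}, {}, {0: "MAJ"})
        assert per_unit == {}
        assert np.all(np.isnan(mea))


class TestPhasePlot:
    def test_sinusoid_traces_ellipse(self):
        t = np.arange(40) / FS
        freq = 500.0
        amp = 20.0
        v, dv = phase_plot(amp * np.sin(2 * np.pi * freq * t), FS)
        # closed form: max |dV/dt| = amp * omega (in uV/ms)
        omega_ms = 2 * np.pi * freq / 1e3
        assert np.max(np.abs(dv)) == pytest.approx(amp * omega_ms, rel=0.05)
        # on-curve check away from the extrema handled by the derivative
        mid = slice(2, -2)
        ellipse = (v[mid] / amp) ** 2 + (dv[mid] / (amp * omega_ms)) ** 2
        assert np.allclose(ellipse, 1.0, atol=0.05)

    def test_constant_snippet_degenerates_to_point(self):
        v, dv = phase_plot(np.full(40, 5.0), FS)
        assert np.allclose(dv, 0.0)

    def test_narrower_template_has_steeper_phase_loop(self):
        tmpl = WaveformTemplate(60.0, 0.35, 18.0)
        _, dv_wide = phase_plot(tmpl.render(FS), FS)
        _, dv_narrow = phase_plot(tmpl.render(FS, width_scale=0.8), FS)
        assert np.max(np.abs(dv_narrow)) > np.max(np.abs(dv_wide))
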