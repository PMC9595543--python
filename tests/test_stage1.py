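"""Stage I: ICA decomposition, component selection, peak detection."""
import numpy as np
import pytest
from scipy.stats import kurtosis as excess_kurtosis

from megspike import (NoCandidatesError, PipelineConfig,
                      detect_component_peaks, ica_decompose, refine_peaks,
                      score_components)
from megspike.data_model import SensorRecording
from megspike.stage1 import CandidatePeaks, ComponentSet, robust_scale


class TestIcaDecompose:
    def test_component_count_and_order(self, preprocessed):
        rec, _ = preprocessed
        cs = ica_decompose(rec, n_components=20, seed=0)
        assert cs.n_components == 20
        assert np.all(np.diff(cs.explained_var) <= 1e-12)

    def test_recovers_planted_topographies(self, scored_components,
                                           spike_recording):
        cs = scored_components
        _, gt = spike_recording
        for u_true, _ in gt.true_atoms:
            cors = [abs(np.corrcoef(u_true, cs.topographies[:, i])[0, 1])
                    for i in range(cs.n_components)]
            assert max(cors) > 0.9

    def test_deterministic_given_seed(self, preprocessed):
        rec, _ = preprocessed
        a = ica_decompose(rec, n_components=20, seed=3)
        b = ica_decompose(rec, n_components=20, seed=3)
        np.testing.assert_allclose(a.topographies, b.topographies)
        np.testing.assert_allclose(a.sources, b.sources)

    def test_too_few_channels_rejected(self):
        rec = SensorRecording(np.random.default_rng(0).standard_normal((5, 100)),
                              200.0, [f"C{i}" for i in range(5)],
                              ["gradiometer"] * 5)
        with pytest.raises(ValueError):
            ica_decompose(rec, n_components=20, seed=0)


def _component_set(fwd, sources, topographies, sensor_type="gradiometer"):
    k = topographies.shape[1]
    ev = np.linspace(1, 0.1, k)
    kurt = excess_kurtosis(sources, axis=1, fisher=True, bias=True)
    return ComponentSet(topographies, sources, 200.0, sensor_type,
                        explained_var=ev, kurtosis=kurt)


class TestComponentSelection:
    """Kurtosis band [1, 10], GOF thresholds 0.80/0.60, override at 0.95."""

    def _make(self, small_fwd, seed, n=10, sensor_type="gradiometer"):
        rng = np.random.default_rng(seed)
        topo = rng.standard_normal((small_fwd.n_channels, n))
        src = rng.standard_normal((n, 4000))
        return topo, src

    def test_dipolar_peaky_component_selected(self, small_fwd):
        topo, src = self._make(small_fwd, 0)
        topo[:, 0] = small_fwd.leadfield[:, 5]  # dipolar: gof = 1 > 0.95
        src[0, ::200] = 12.0  # sparse transients: kurtosis in band
        cs = _component_set(small_fwd, src, topo)
        cs = score_components(cs, small_fwd, PipelineConfig())
        assert cs.selected[0]
        assert cs.gof[0] > 0.95

    def test_override_ignores_kurtosis(self, small_fwd):
        """GOF above 0.95 selects even a Gaussian (kurtosis ~ 0) component."""
        topo, src = self._make(small_fwd, 1)
        topo[:, 2] = small_fwd.leadfield[:, 30]
        cs = _component_set(small_fwd, src, topo)
        assert abs(cs.kurtosis[2]) < 0.2  # below the band
        cs = score_components(cs, small_fwd, PipelineConfig())
        assert cs.selected[2]

    def test_low_gof_rejected_despite_kurtosis(self, small_fwd):
        topo, src = self._make(small_fwd, 2)
        src[1, ::150] = 10.0  # peaky but spatially random
        cs = _component_set(small_fwd, src, topo)
        cs.topographies[:, 0] = small_fwd.leadfield[:, 3]  # keep one selectable
        src[0, ::150] = 10.0
        cs = score_components(cs, small_fwd, PipelineConfig())
        assert cs.kurtosis[1] > 1.0  # peaky, so only the GOF gate rejects it
        assert cs.gof[1] < 0.60
        assert not cs.selected[1]

    def test_no_candidates_raises(self, small_fwd):
        topo, src = self._make(small_fwd, 3)
        cs = _component_set(small_fwd, src, topo)
        with pytest.raises(NoCandidatesError):
            score_components(cs, small_fwd, PipelineConfig())

    def test_kurtosis_separates_noise_from_transients(self):
        rng = np.random.default_rng(0)
        gauss = rng.standard_normal(200 * 600)
        assert abs(excess_kurtosis(gauss)) < 0.2
        spiky = rng.standard_normal(200 * 600)
        spiky[::400] += 15.0
        assert excess_kurtosis(spiky) > 1.0


class TestPeakDetection:
    def test_robust_scale_constant_series(self):
        assert np.all(robust_scale(np.full(100, 3.7)) == 0.0)

    def test_adaptive_threshold_reaches_min_peaks(self, scored_components):
        cfg = PipelineConfig(min_peaks=50)
        peaks = detect_component_peaks(scored_components, cfg)
        assert peaks.n_peaks >= 50

    def test_isolated_large_peaks_found_at_floor(self, small_fwd):
        """10 isolated in-band transients, nothing else above the floor."""
        sfreq = 200.0
        t = np.arange(int(60 * sfreq)) / sfreq
        x = np.sin(2 * np.pi * 30 * t)  # in-band baseline sets the IQR
        centers = np.linspace(5, 55, 10)
        for c in centers:
            # single half-cosine lobe: one dominant peak above the floor
            m = np.abs(t - c) <= 1 / 160.0
            x[m] += 6.0 * np.cos(2 * np.pi * 40 * (t[m] - c))
        topo = small_fwd.leadfield[:, [0]]
        cs = ComponentSet(topo, x[None, :], sfreq, "gradiometer",
                          explained_var=np.array([1.0]),
                          kurtosis=np.array([5.0]),
                          selected=np.array([True]))
        peaks = detect_component_peaks(cs, PipelineConfig())
        assert peaks.threshold == min(PipelineConfig().peak_threshold_grid)
        assert peaks.n_peaks == 10
        found = np.sort(peaks.peaks[0]) / sfreq
        np.testing.assert_allclose(found, centers, atol=0.02)

    def test_constant_component_yields_no_peaks(self, small_fwd):
        cs = ComponentSet(small_fwd.leadfield[:, [0]],
                          np.zeros((1, 4000)), 200.0, "gradiometer",
                          explained_var=np.array([1.0]),
                          kurtosis=np.array([0.0]),
                          selected=np.array([True]))
        with pytest.raises(NoCandidatesError):
            detect_component_peaks(cs, PipelineConfig())


class TestRefinePeaks:
    def _recording_with_patterns(self, small_fwd, samples, mixes, n=4000):
        """Zeros except dipolar bursts at given samples with given purity."""
        rng = np.random.default_rng(0)
        data = 1e-6 * rng.standard_normal((small_fwd.n_channels, n))
        pulse = np.hanning(11)
        for s, mix in zip(samples, mixes):
            g = small_fwd.leadfield[:, 8]
            g = g / np.linalg.norm(g)
            noise = rng.standard_normal(g.size)
            noise -= (noise @ g) * g
            noise /= np.linalg.norm(noise)
            pattern = mix * g + (1 - mix) * noise
            data[:, s - 5:s + 6] += np.outer(pattern, pulse)
        return SensorRecording(data, 200.0,
                               [f"C{i}" for i in range(small_fwd.n_channels)],
                               ["gradiometer"] * small_fwd.n_channels)

    def _peaks(self, samples):
        arr = np.asarray(samples)
        return CandidatePeaks({0: arr}, {0: np.ones(arr.size)}, 2.0, 200.0,
                              "gradiometer")

    def test_refractory_keeps_best_gof(self, small_fwd):
        # 0.3 s apart: pure dipole (high gof) vs mixed pattern (low gof)
        rec = self._recording_with_patterns(small_fwd, [1000, 1060],
                                            [1.0, 0.6])
        ev = refine_peaks(self._peaks([1000, 1060]), rec, small_fwd)
        assert len(ev) == 1
        assert ev.samples[0] == 1000

    def test_separated_events_both_survive(self, small_fwd):
        rec = self._recording_with_patterns(small_fwd, [1000, 1120],
                                            [1.0, 0.6])
        ev = refine_peaks(self._peaks([1000, 1120]), rec, small_fwd)
        assert len(ev) == 2

    def test_window_out_of_bounds_dropped(self, small_fwd):
        rec = self._recording_with_patterns(small_fwd, [1000], [1.0])
        ev = refine_peaks(self._peaks([2, 1000]), rec, small_fwd)
        assert list(ev.samples) == [1000]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_output_separation_property(self, preprocessed, small_fwd, seed):
        """Whatever the input peaks, refined events are > 0.5 s apart."""
        rec, _ = preprocessed
        rng = np.random.default_rng(seed)
        samples = np.unique(rng.integers(100, rec.n_samples - 100, 200))
        ev = refine_peaks(self._peaks(samples), rec, small_fwd)
        if len(ev) > 1:
            assert np.diff(ev.times).min() > 0.5

    def test_planted_events_recovered(self, preprocessed, small_fwd):
        """End-to-end Stage I finds the planted spikes with high recall."""
        rec, gt = preprocessed
        cfg = PipelineConfig(min_peaks=50)
        cs = ica_decompose(rec, 20, seed=0)
        cs = score_components(cs, small_fwd, cfg)
        peaks = detect_component_peaks(cs, cfg)
        ev = refine_peaks(peaks, rec, small_fwd, cfg)
        truth = gt.all_event_times
        hits = sum(np.min(np.abs(ev.times - t)) <= 0.025 for t in truth)
        assert hits / len(truth) >= 0.9
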