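"""Filterbank construction, CWT, coherence, broadband TVFC, AR1 thresholds."""

import numpy as np
import pytest

import brainstates as bs
from brainstates.coherence import (Filterbank, coherence_significance_threshold,
                                   morlet_kernel, wavelet_coherence_pair)
from brainstates.synthetic import Block


class TestFilterbank:
    def test_default_bank_endpoints(self):
        fb = bs.build_filterbank(0.007, 0.15, 15, 6)
        assert fb.n_scales == 15
        assert np.isclose(fb.center_freqs[-1], 0.007)
        assert np.isclose(fb.center_freqs[0], 0.15)

    def test_two_scales_are_the_endpoints(self):
        fb = bs.build_filterbank(0.01, 0.1, 2, 6)
        assert np.allclose(sorted(fb.center_freqs), [0.01, 0.1])

    def test_geometric_spacing(self):
        fb = bs.build_filterbank(0.007, 0.15, 15, 6)
        ratios = fb.center_freqs[1:] / fb.center_freqs[:-1]
        assert np.allclose(ratios, ratios[0], rtol=1e-12)

    def test_scale_frequency_conversion(self):
        fb = bs.build_filterbank(0.01, 0.1, 5, 6)
        assert np.allclose(fb.omega0 / (2 * np.pi * fb.scales), fb.center_freqs)

    def test_nyquist_error_cites_tr(self):
        with pytest.raises(ValueError, match="TR=1.5"):
            bs.build_filterbank(0.01, 0.4, 5, 6, tr=1.5)

    def test_omega0_floor(self):
        with pytest.raises(ValueError, match="omega0"):
            bs.build_filterbank(0.01, 0.1, 5, omega0=2)


def _sine_series(freq, T=1200, tr=1.5, n_regions=1):
    t = np.arange(T) * tr
    sig = np.tile(np.sin(2 * np.pi * freq * t), (n_regions, 1))
    return bs.ParcelSeries("s", sig, tr, [f"r{i}" for i in range(n_regions)], [])


class TestCWT:
    def test_zero_signal_zero_coefficients(self):
        fb = bs.build_filterbank()
        series = bs.ParcelSeries("z", np.zeros((2, 1200)), 1.5, ["a", "b"], [])
        spec = bs.cwt(series, fb)
        assert np.abs(spec.coeffs).max() == 0.0

    def test_linearity(self, rng):
        fb = bs.build_filterbank(0.02, 0.1, 6, 6)
        f = rng.normal(size=(1, 900))
        g = rng.normal(size=(1, 900))
        mk = lambda x: bs.ParcelSeries("x", x, 1.5, ["a"], [])
        wa = bs.cwt(mk(2.0 * f + 3.0 * g), fb).coeffs
        wb = 2.0 * bs.cwt(mk(f), fb).coeffs + 3.0 * bs.cwt(mk(g), fb).coeffs
        assert np.allclose(wa, wb, atol=1e-10)

    def test_sinusoid_peaks_at_matching_scale(self):
        fb = bs.build_filterbank(0.01, 0.12, 9, 6)
        target = 4  # middle scale
        series = _sine_series(fb.center_freqs[target], T=2400)
        spec = bs.cwt(series, fb)
        mid = spec.coeffs.shape[-1] // 2
        assert np.argmax(np.abs(spec.coeffs[0, :, mid])) == target

    def test_too_short_series_errors(self):
        fb = bs.build_filterbank()
        series = bs.ParcelSeries("s", np.zeros((1, 100)), 1.5, ["a"], [])
        with pytest.raises(ValueError, match="support"):
            bs.cwt(series, fb)


class TestCoherencePair:
    def _spec(self, sig, fb, tr=1.5):
        series = bs.ParcelSeries("s", sig, tr, [str(i) for i in range(len(sig))], [])
        return bs.cwt(series, fb)

    def test_self_coherence_is_one(self, rng):
        fb = bs.build_filterbank(0.02, 0.1, 6, 6)
        spec = self._spec(rng.normal(size=(1, 900)), fb)
        r2 = wavelet_coherence_pair(spec.coeffs[0], spec.coeffs[0],
                                    fb.scales, 1.5)
        assert np.allclose(r2, 1.0, atol=1e-9)

    def test_sign_flip_invariant(self, rng):
        fb = bs.build_filterbank(0.02, 0.1, 6, 6)
        x = rng.normal(size=(1, 900))
        sx = self._spec(x, fb)
        sy = self._spec(-x, fb)
        r2 = wavelet_coherence_pair(sx.coeffs[0], sy.coeffs[0], fb.scales, 1.5)
        assert np.allclose(r2, 1.0, atol=1e-9)

    def test_independent_noise_moderate_coherence(self, rng):
        """Smoothing biases white-noise coherence upward, but mid-scale mean
        stays well below 1 for independent signals."""
        fb = bs.build_filterbank(0.02, 0.1, 8, 6)
        sig = rng.normal(size=(2, 4096))
        spec = self._spec(sig, fb, tr=1.0)
        r2 = wavelet_coherence_pair(spec.coeffs[0], spec.coeffs[1],
                                    fb.scales, 1.0)
        mid = r2[2:-2, 500:-500]
        assert mid.mean() < 0.35

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            wavelet_coherence_pair(np.zeros((3, 10)), np.zeros((4, 10)),
                                   np.ones(3), 1.5)


class TestPowerWeighted:
    def test_unit_coherence_gives_unit_mean(self):
        r2 = np.ones((4, 7))
        w = np.random.default_rng(0).uniform(0.1, 2.0, size=(4, 7))
        assert np.allclose(bs.power_weighted_tvfc(r2, w), 1.0)

    def test_equal_weights_average(self):
        r2 = np.array([[1.0], [0.0]])
        w = np.array([[1.0], [1.0]])
        assert np.isclose(bs.power_weighted_tvfc(r2, w)[0], 0.5)

    def test_zero_weight_scale_ignored(self):
        r2 = np.array([[0.8], [0.3]])
        w = np.array([[2.0], [0.0]])
        assert np.isclose(bs.power_weighted_tvfc(r2, w)[0], 0.8)

    def test_all_zero_weights_give_zero(self):
        out = bs.power_weighted_tvfc(np.full((3, 2), 0.5), np.zeros((3, 2)))
        assert np.allclose(out, 0.0)


class TestComputeTVFC:
    def test_trim_arithmetic(self, small_tvfc, small_study):
        _, series = small_study
        assert small_tvfc.retained_scales.size == 15 - 2 * 2
        assert small_tvfc.n_points == series.n_samples - 2 * 120
        assert small_tvfc.retained_time_index[0] == 120

    def test_graphs_symmetric_zero_diagonal_bounded(self, small_tvfc):
        g = small_tvfc.graphs
        assert np.allclose(g, g.transpose(0, 2, 1))
        assert np.allclose(np.diagonal(g, axis1=1, axis2=2), 0.0)
        assert g.min() >= 0.0 and g.max() <= 1.0

    def test_duplicate_region_distance_zero(self, rng, filterbank):
        x = rng.normal(size=900)
        sig = np.vstack([x, x, rng.normal(size=900)])
        series = bs.ParcelSeries("d", sig, 1.5, ["a", "a2", "b"], [])
        tv = bs.compute_tvfc(series, filterbank)
        assert np.abs(tv.graphs[:, 0, 1]).max() < 1e-6

    def test_shared_latent_closer_than_independent(self, rng):
        """Two regions driven by one latent oscillation sit closer to each
        other than either sits to an independent-noise region."""
        from brainstates.synthetic import _band_limited_noise
        T = 1000
        lat = _band_limited_noise(T, 1.5, (0.01, 0.08), rng)
        sig = np.vstack([
            3 * lat + rng.normal(size=T),
            3 * lat + rng.normal(size=T),
            rng.normal(size=T),
        ])
        series = bs.ParcelSeries("t", sig, 1.5, ["a", "b", "c"], [])
        tv = bs.compute_tvfc(series, bs.build_filterbank(tr=1.5))
        d_ab = np.median(tv.graphs[:, 0, 1])
        d_ac = np.median(tv.graphs[:, 0, 2])
        d_bc = np.median(tv.graphs[:, 1, 2])
        assert d_ab < d_ac and d_ab < d_bc

    def test_pearson_limit_monotone_in_noise(self, rng):
        """Scaled copies plus shrinking noise: broadband coherence -> 1."""
        T = 800
        base = rng.normal(size=T)
        means = []
        for sd in (2.0, 1.0, 0.5, 0.1, 0.01):
            sig = np.vstack([base, 0.5 * base + sd * rng.normal(size=T)])
            series = bs.ParcelSeries("p", sig, 1.5, ["a", "b"], [])
            tv = bs.compute_tvfc(series, bs.build_filterbank(tr=1.5))
            means.append(1.0 - tv.graphs[:, 0, 1].mean())
        assert all(a < b for a, b in zip(means, means[1:]))
        assert means[-1] > 0.95

    def test_over_trimming_errors(self, small_study, filterbank):
        _, series = small_study
        with pytest.raises(ValueError, match="scale"):
            bs.compute_tvfc(series, filterbank, trim_scales=8)


@pytest.fixture(scope="module")
def cfg():
    return bs.StudyConfig(n_volunteers=1, n_regions=4, seed=2,
                         block_layout=[Block("rest", 600.0, 0.0)])


class TestSignificanceThreshold:

    def test_quantile_extremes_are_order_statistics(self, cfg):
        fb = bs.build_filterbank(tr=cfg.tr)
        kw = dict(n_surrogates=50, n_samples=800, trim_time=120, seed=5)
        lo = coherence_significance_threshold(cfg, fb, quantile=0.0, **kw)
        hi = coherence_significance_threshold(cfg, fb, quantile=1.0, **kw)
        mid = coherence_significance_threshold(cfg, fb, quantile=0.5, **kw)
        assert lo <= mid <= hi
        assert 0.0 <= lo and hi <= 1.0

    def test_wider_smoothing_lowers_the_coherence_bar(self, cfg):
        """More smoothing suppresses spurious coherence between independent
        AR1 pairs, so the coherence an edge must reach to clear the null
        (1 - distance threshold) decreases monotonically."""
        fb = bs.build_filterbank(tr=cfg.tr)
        kw = dict(n_surrogates=60, n_samples=800, trim_time=120,
                  quantile=0.05, seed=6)
        bars = [
            1.0 - coherence_significance_threshold(cfg, fb,
                                                   time_sigma_factor=tsf, **kw)
            for tsf in (0.5, 1.0, 2.0)
        ]
        assert bars[0] > bars[1] > bars[2]

    def test_too_few_surrogates_error(self, cfg):
        fb = bs.build_filterbank(tr=cfg.tr)
        with pytest.raises(ValueError, match="50"):
            coherence_significance_threshold(cfg, fb, n_surrogates=10)
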