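"""Log-normal mixture decomposition and intensity-binned analysis."""

import numpy as np
import pytest

import endotrack as et
from endotrack.mixture import lognormal_mean


class TestLognormalMean:
    @pytest.mark.parametrize("mu", [0.1, 0.33, 1.0, 2.5])
    def test_degenerate_sigma_returns_mu(self, mu):
        assert lognormal_mean(mu, 0.0) == mu

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            lognormal_mean(1.0, -0.1)
        with pytest.raises(ValueError):
            lognormal_mean(0.0, 0.5)
        with pytest.raises(ValueError):
            lognormal_mean(float("nan"), 0.5)

    @pytest.mark.parametrize("mu", [0.1, 0.3, 1.0, 2.0])
    @pytest.mark.parametrize("sigma", [0.1, 0.5, 1.0, 1.4])
    def test_agrees_with_monte_carlo(self, mu, sigma):
        """Analytic mean within 3 standard errors of 1e6 draws."""
        rng = np.random.default_rng(hash((mu, sigma)) % 2**31)
        draws = rng.lognormal(np.log(mu), sigma, 1_000_000)
        se = draws.std() / np.sqrt(draws.size)
        assert abs(lognormal_mean(mu, sigma) - draws.mean()) < 3 * se

    def test_trkb_slow_component_value(self):
        """(0.2, 1.08) evaluates to ~0.358, cross-checked by simulation."""
        analytic = lognormal_mean(0.2, 1.08)
        rng = np.random.default_rng(1234)
        draws = rng.lognormal(np.log(0.2), 1.08, 2_000_000)
        assert analytic == pytest.approx(draws.mean(), rel=0.005)
        assert analytic == pytest.approx(0.358, abs=0.001)


class TestFitMixture:
    def test_two_component_recovery(self):
        """0.7 LogN(ln 0.33, 0.98) + 0.3 LogN(ln 1.6, 0.57), n=2e4:
        k=2 selected and parameters recovered."""
        rng = np.random.default_rng(42)
        n = 20_000
        comp = rng.random(n) < 0.3
        v = np.where(
            comp,
            rng.lognormal(np.log(1.6), 0.57, n),
            rng.lognormal(np.log(0.33), 0.98, n),
        )
        fit = et.fit_mixture(v, k_max=3)
        assert fit.k == 2
        slow, fast = fit.components
        assert slow.mu == pytest.approx(0.33, rel=0.10)
        assert slow.sigma == pytest.approx(0.98, rel=0.10)
        assert fast.mu == pytest.approx(1.6, rel=0.10)
        assert fast.sigma == pytest.approx(0.57, rel=0.10)
        assert slow.weight == pytest.approx(0.7, abs=0.10)
        assert fast.weight == pytest.approx(0.3, abs=0.10)

    def test_single_component_selected(self):
        """>= 90% of 20 single-log-normal samples select k=1."""
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            v = rng.lognormal(np.log(0.5), 0.7, 5000)
            ok += et.fit_mixture(v, k_max=3).k == 1
        assert ok >= 18

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(3)
        v = rng.lognormal(np.log(0.8), 0.6, 3000)
        fit = et.fit_mixture(v, k_max=3)
        assert fit.weights.sum() == pytest.approx(1.0)

    def test_mean_speed_consistent_with_formula(self):
        rng = np.random.default_rng(4)
        v = rng.lognormal(np.log(0.5), 0.8, 5000)
        fit = et.fit_mixture(v, k_max=2)
        for c in fit.components:
            assert c.mean_speed == pytest.approx(lognormal_mean(c.mu, c.sigma))

    def test_self_consistency(self):
        """Refitting data drawn from a returned fit reproduces it."""
        rng = np.random.default_rng(6)
        n = 30_000
        comp = rng.random(n) < 0.35
        v = np.where(
            comp,
            rng.lognormal(np.log(1.5), 0.4, n),
            rng.lognormal(np.log(0.3), 0.8, n),
        )
        fit1 = et.fit_mixture(v, k_max=2)
        draws = []
        for c in fit1.components:
            m = int(round(n * c.weight))
            draws.append(rng.lognormal(np.log(c.mu), c.sigma, m))
        fit2 = et.fit_mixture(np.concatenate(draws), k_max=2)
        for c1, c2 in zip(fit1.components, fit2.components):
            assert c2.mu == pytest.approx(c1.mu, rel=0.1)
            assert c2.sigma == pytest.approx(c1.sigma, rel=0.15)

    def test_out_of_range_samples_rejected(self):
        with pytest.raises(ValueError, match="fit_range"):
            et.fit_mixture(np.full(100, 50.0))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="50"):
            et.fit_mixture(np.linspace(0.1, 1.0, 20))


class TestIntensityBinnedAnalysis:
    @staticmethod
    def _segments(coupling, seed=15):
        model = et.MotionModel(p_slow_to_fast=0.05)
        cfg = et.SimulationConfig(
            n_frames=600, n_endosomes=80, axon_length_px=100000,
            intensity_motility_coupling=coupling, seed=seed,
        )
        truth = et.simulate_tracks(model, cfg)
        tracks = truth.tracks.rename(
            columns={"x_px": "x", "y_px": "y", "intensity": "integral_intensity"}
        )
        return et.extract_all_segments(tracks, cfg.pixel_size_um, cfg.frame_interval_s)

    def test_positive_coupling_raises_event_counts_with_intensity(self):
        """Brighter endosomes start more fast runs: the number of movement
        events per intensity bin trends up (Spearman)."""
        from scipy.stats import spearmanr

        profile = et.intensity_binned_analysis(
            self._segments(0.95), n_bins=5, binning="quantile"
        )["retrograde"]
        rho, p = spearmanr(np.arange(5), profile.n_events)
        assert rho > 0 and p < 0.05

    def test_null_coupling_shows_no_event_trend(self):
        from scipy.stats import spearmanr

        profile = et.intensity_binned_analysis(
            self._segments(0.0), n_bins=5, binning="quantile"
        )["retrograde"]
        rho, p = spearmanr(np.arange(5), profile.n_events)
        assert p > 0.05 or abs(rho) < 0.9

    def test_bin_floor_reported_empty(self):
        segs = self._segments(0.0)
        profile = et.intensity_binned_analysis(
            segs, n_bins=5, binning="quantile", min_events=10**7
        )["retrograde"]
        assert np.all(np.isnan(profile.fast_fraction))
        assert profile.n_events.sum() > 0

    def test_single_direction_profiles_have_bin_edges_covering_data(self):
        segs = self._segments(0.5)
        profiles = et.intensity_binned_analysis(segs, n_bins=4, binning="quantile")
        intens = [s.mean_intensity for s in segs]
        for p in profiles.values():
            assert p.bin_edges[0] <= min(intens)
            assert p.bin_edges[-1] >= max(intens)

    def test_requires_two_bins(self):
        with pytest.raises(ValueError):
            et.intensity_binned_analysis(self._segments(0.0), n_bins=1)
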