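"""Gaussian-mixture fitting, two-state decomposition, reduced chi-square."""

import numpy as np
import pytest

import deermix as dm


class TestChi2Reduced:
    def test_exact_model_gives_zero(self, undocked_clean):
        tr = dm.DeerTrace(
            undocked_clean.times, undocked_clean.signal, noise_sd=0.02
        )
        assert dm.chi2_reduced(tr, undocked_clean.signal, q=1) == 0.0

    def test_unit_residuals_give_one(self):
        times = np.linspace(0, 1, 64)
        v = np.ones(64)
        tr = dm.DeerTrace(times, v, noise_sd=0.1)
        assert dm.chi2_reduced(tr, v - 0.1, q=0) == pytest.approx(1.0)

    def test_printed_formula_arithmetic(self):
        # N = 4, residuals (1, 2, 1, 0), s = 1, q = 2 -> (1+4+1+0)/(4-2) = 3
        times = np.array([0.0, 1.0, 2.0, 3.0])
        v = np.array([1.0, 2.0, 1.0, 0.0])
        tr = dm.DeerTrace(times, v, noise_sd=1.0)
        assert dm.chi2_reduced(tr, np.zeros(4), q=2) == pytest.approx(3.0)

    def test_too_many_parameters_rejected(self):
        tr = dm.DeerTrace(np.linspace(0, 1, 4), np.ones(4), noise_sd=1.0)
        with pytest.raises(ValueError):
            dm.chi2_reduced(tr, np.ones(4), q=4)

    def test_missing_noise_without_estimation_rejected(self, undocked_clean):
        with pytest.raises(ValueError):
            dm.chi2_reduced(undocked_clean, undocked_clean.signal, q=1, estimate=False)

    def test_concentrates_near_one_at_true_model(self, grid, acq, times):
        dist = dm.two_state_distribution(0.5, dm.DOCKED, dm.UNDOCKED, grid)
        clean = dm.simulate_trace(dist, acq, times)
        chis = [
            dm.chi2_reduced(dm.add_noise(clean, dm.NoiseModel(50, s)), clean.signal, q=0)
            for s in range(50)
        ]
        assert all(0.7 <= c <= 1.4 for c in chis)


class TestFitGaussians:
    def test_noiseless_round_trip_within_half_percent(self, grid, acq, times):
        comp = dm.GaussianComponent(35.0, 4.0)
        tr = dm.simulate_trace(dm.gaussian_distribution(comp, grid), acq, times)
        res = dm.fit_gaussians(tr, 1, grid=grid)
        assert res.params["mean1"] == pytest.approx(35.0, rel=0.005)
        assert res.params["sigma1"] == pytest.approx(4.0, rel=0.005)
        assert res.params["lambda"] == pytest.approx(0.3, abs=0.005)

    def test_correct_model_chi2_below_two(self, grid, acq, times):
        tr = dm.add_noise(
            dm.simulate_trace(dm.gaussian_distribution(dm.UNDOCKED, grid), acq, times),
            dm.NoiseModel(50, 9),
        )
        res = dm.fit_gaussians(tr, 1, grid=grid)
        assert res.chi2_nu <= 2.0

    def test_all_fixed_matches_two_state_fit(self, grid, acq, times):
        tr = dm.variant_trace("H378N_EN_dark", acq, times, dm.NoiseModel(50, 5))
        fix = {
            "mean1": dm.UNDOCKED.mean,
            "sigma1": dm.UNDOCKED.sigma,
            "mean2": dm.DOCKED.mean,
            "sigma2": dm.DOCKED.sigma,
        }
        free = dm.fit_gaussians(tr, 2, grid=grid, fix=fix)
        ts = dm.two_state_fit(tr, dm.DOCKED, dm.UNDOCKED, grid=grid)
        assert free.params["frac1"] == pytest.approx(ts.fraction_undocked, abs=1e-6)
        assert free.chi2_nu == pytest.approx(ts.chi2_nu, rel=1e-6)

    def test_unconstrained_fit_converges_to_registry_components(self, acq, times):
        # free 2-Gaussian fits on mid-fraction variant traces find the
        # docked/undocked components without being told them
        means_d, sigmas_d, means_u, sigmas_u = [], [], [], []
        for seed in (1, 2, 3, 4, 5):
            tr = dm.variant_trace("H378N_EN_dark", acq, times, dm.NoiseModel(50, seed))
            res = dm.fit_gaussians(tr, 2)
            assert res.converged
            p = res.params
            lo, hi = sorted(
                [(p["mean1"], p["sigma1"]), (p["mean2"], p["sigma2"])]
            )
            means_d.append(lo[0])
            sigmas_d.append(lo[1])
            means_u.append(hi[0])
            sigmas_u.append(hi[1])
        assert np.mean(means_d) == pytest.approx(dm.DOCKED.mean, abs=2.0)
        assert np.mean(means_u) == pytest.approx(dm.UNDOCKED.mean, abs=2.0)
        assert np.mean(sigmas_d) == pytest.approx(dm.DOCKED.sigma, abs=1.5)
        assert np.mean(sigmas_u) == pytest.approx(dm.UNDOCKED.sigma, abs=1.5)

    def test_bad_component_count_rejected(self, undocked_clean):
        with pytest.raises(ValueError):
            dm.fit_gaussians(undocked_clean, 4)


class TestTwoStateFit:
    def test_zero_fraction_boundary_recovery(self, grid, acq, times):
        tr = dm.variant_trace("EN_dark", acq, times, dm.NoiseModel(50, 1))
        ts = dm.two_state_fit(tr, dm.DOCKED, dm.UNDOCKED, grid=grid)
        assert ts.fraction_undocked < 0.02

    def test_table_fraction_recovery_within_uncertainty(self, grid, acq, times):
        # H378N/L405E/C416N generated at f = 0.63: the seed-averaged
        # estimate recovers the generating value within its spread
        vals = [
            dm.two_state_fit(
                dm.variant_trace("H378N_EN_dark", acq, times, dm.NoiseModel(50, s)),
                dm.DOCKED,
                dm.UNDOCKED,
                grid=grid,
            ).fraction_undocked
            for s in range(1, 11)
        ]
        band = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 0.63) < max(3 * band, 0.02)

    def test_relabeling_equivariance(self, grid, acq, times):
        tr = dm.variant_trace("H378K_EN_dark", acq, times, dm.NoiseModel(50, 2))
        ab = dm.two_state_fit(tr, dm.DOCKED, dm.UNDOCKED, grid=grid).fraction_undocked
        ba = dm.two_state_fit(tr, dm.UNDOCKED, dm.DOCKED, grid=grid).fraction_undocked
        assert ab == pytest.approx(1.0 - ba, abs=1e-3)

    def test_identical_components_rejected(self, undocked_clean):
        with pytest.raises(ValueError):
            dm.two_state_fit(undocked_clean, dm.DOCKED, dm.DOCKED)

    def test_uncertainty_positive_and_ordered(self, grid, acq, times):
        # doubling the noise should not shrink the reported uncertainty
        tr_lo = dm.variant_trace("H378R_EN_dark", acq, times, dm.NoiseModel(100, 3))
        tr_hi = dm.variant_trace("H378R_EN_dark", acq, times, dm.NoiseModel(25, 3))
        sd_lo = dm.two_state_fit(tr_lo, dm.DOCKED, dm.UNDOCKED, grid=grid).stderr
        sd_hi = dm.two_state_fit(tr_hi, dm.DOCKED, dm.UNDOCKED, grid=grid).stderr
        assert 0 < sd_lo < sd_hi


class TestLincombFit:
    def test_endpoint_recovery(self, undocked_clean, docked_clean):
        a, _ = dm.lincomb_fit(undocked_clean, undocked_clean, docked_clean, noise_sd=0.02)
        assert a == pytest.approx(1.0, abs=1e-6)

    def test_exact_mixture_recovery(self, undocked_clean, docked_clean):
        target = dm.DeerTrace(
            undocked_clean.times,
            0.5 * undocked_clean.signal + 0.5 * docked_clean.signal,
            noise_sd=0.02,
        )
        a, res = dm.lincomb_fit(target, undocked_clean, docked_clean)
        assert a == pytest.approx(0.5, abs=1e-9)
        assert res.chi2_nu == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_two_state_fit(self, grid, acq, times, undocked_clean, docked_clean):
        for name in ("H378R_EN_dark", "H378K_light"):
            tr = dm.variant_trace(name, acq, times, dm.NoiseModel(50, 8))
            a_lc, _ = dm.lincomb_fit(tr, undocked_clean, docked_clean)
            a_ts = dm.two_state_fit(tr, dm.DOCKED, dm.UNDOCKED, grid=grid).fraction_undocked
            assert abs(a_lc - a_ts) < 0.05

    def test_identical_bases_rejected(self, undocked_clean):
        with pytest.raises(ValueError):
            dm.lincomb_fit(undocked_clean, undocked_clean, undocked_clean)

    def test_resampling_onto_target_axis(self, grid, acq, undocked_clean, docked_clean):
        coarse = dm.default_times(3.0, 128)
        dist = dm.two_state_distribution(0.7, dm.DOCKED, dm.UNDOCKED, grid)
        target = dm.add_noise(dm.simulate_trace(dist, acq, coarse), dm.NoiseModel(50, 4))
        a, _ = dm.lincomb_fit(target, undocked_clean, docked_clean)
        assert a == pytest.approx(0.7, abs=0.05)
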