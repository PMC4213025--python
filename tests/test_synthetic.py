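"""Generators: power-law variates, walkers, colored noise."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import termwalk as tw


class TestPowerlawVariates:
    def test_lower_bound_and_support(self):
        x = tw.powerlaw_variates(2.5, 3.0, 10**4, seed=1)
        assert (x >= 3.0).all()

    def test_closed_form_median(self):
        # median of P(x) ~ x^-2.5, x_min=1 is 2**(1/1.5)
        x = tw.powerlaw_variates(2.5, 1.0, 10**6, seed=2)
        assert np.median(x) == pytest.approx(2 ** (1 / 1.5), rel=0.01)

    def test_matches_analytic_cdf(self):
        x = tw.powerlaw_variates(2.5, 1.0, 10**5, seed=4)
        ks = stats.kstest(x, lambda v: 1 - v ** (1 - 2.5)).statistic
        assert ks < 0.01

    def test_reproducible(self):
        a = tw.powerlaw_variates(2.2, 0.5, 100, seed=9)
        b = tw.powerlaw_variates(2.2, 0.5, 100, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_nonnormalizable_rejected(self):
        with pytest.raises(ValueError):
            tw.powerlaw_variates(1.0, 1.0, 10)

    def test_running_mean_divergence_vs_convergence(self):
        # infinite-mean regime (alpha<=2): the running mean keeps growing;
        # finite-mean regime (alpha>2): it settles near the analytic mean
        x = tw.powerlaw_variates(1.5, 1.0, 10**6, seed=11)
        m = np.cumsum(x) / np.arange(1, len(x) + 1)
        assert m[-1] > 3.0 * m[10**4 - 1]
        y = tw.powerlaw_variates(2.5, 1.0, 10**6, seed=11)
        m = np.cumsum(y) / np.arange(1, len(y) + 1)
        analytic = (2.5 - 1) / (2.5 - 2)  # = 3
        assert m[-1] == pytest.approx(analytic, rel=0.05)
        assert abs(m[-1] / m[10**4 - 1] - 1) < 0.2

    @given(st.floats(1.5, 3.0), st.floats(0.1, 10.0))
    def test_support_property(self, alpha, x_min):
        x = tw.powerlaw_variates(alpha, x_min, 200, seed=0)
        assert (x >= x_min).all()


class TestSimulateWalker:
    def test_ballistic_exact(self, ballistic_track):
        traj = ballistic_track
        r = np.hypot(traj.x - traj.x[0], traj.y - traj.y[0])
        k = np.arange(traj.n_samples)
        np.testing.assert_allclose(r, k * 10.0 * 0.5, rtol=1e-9, atol=1e-6)

    def test_brownian_msd_exponent(self, brownian_track_1e5):
        curve = tw.msd(brownian_track_1e5, tw.default_delays(brownian_track_1e5))
        fit = tw.fit_anomalous_exponent(curve)
        assert fit.exponent == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("mu,expected,tol", [(2.2, 1.8, 0.1), (2.5, 1.5, 0.1)])
    def test_levy_msd_recovery(self, mu, expected, tol):
        cfg = tw.SimConfig(
            model="levy_walk", mu=mu, p_wait=0.0, n_samples=10**6,
            arena_diameter=None, boundary="none", seed=11,
        )
        traj = tw.simulate_walker(cfg)
        lags = np.unique(np.round(np.geomspace(2, 1000, 60)).astype(int))
        fit = tw.fit_anomalous_exponent(
            tw.msd(traj, lags * traj.dt), window=(1.0, 500.0)
        )
        assert fit.exponent == pytest.approx(expected, abs=tol)

    def test_levy_msd_at_ballistic_boundary(self):
        # at mu=2 the MSD picks up a log correction (~t^2/ln t), so the
        # measured slope sits slightly below the nominal 4-mu=2
        cfg = tw.SimConfig(
            model="levy_walk", mu=2.0, p_wait=0.0, n_samples=10**6,
            arena_diameter=None, boundary="none", seed=11,
        )
        traj = tw.simulate_walker(cfg)
        lags = np.unique(np.round(np.geomspace(2, 1000, 60)).astype(int))
        fit = tw.fit_anomalous_exponent(
            tw.msd(traj, lags * traj.dt), window=(1.0, 500.0)
        )
        assert 1.80 <= fit.exponent <= 2.0

    @pytest.mark.parametrize("boundary", ["reflect", "follow"])
    def test_confinement_keeps_walker_inside(self, boundary):
        cfg = tw.SimConfig(
            model="levy_walk", mu=2.1, p_wait=0.2, n_samples=20000,
            arena_diameter=205.0, boundary=boundary, seed=6,
        )
        traj = tw.simulate_walker(cfg)
        assert (traj.radius_from_center() <= 102.5 + 1e-9).all()

    def test_brownian_confinement(self):
        cfg = tw.SimConfig(
            model="brownian", n_samples=20000, arena_diameter=55.0,
            boundary="reflect", seed=6,
        )
        traj = tw.simulate_walker(cfg)
        assert (traj.radius_from_center() <= 27.5 + 1e-9).all()

    def test_reproducible(self):
        cfg = tw.SimConfig(model="levy_walk", n_samples=3000, seed=44)
        a = tw.simulate_walker(cfg)
        b = tw.simulate_walker(cfg)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)

    def test_boundary_without_arena_rejected(self):
        with pytest.raises(ValueError, match="arena"):
            tw.SimConfig(arena_diameter=None, boundary="reflect")

    def test_waiting_bouts_present_when_requested(self):
        cfg = tw.SimConfig(
            model="levy_walk", p_wait=0.5, nu=2.6, n_samples=50000,
            arena_diameter=None, boundary="none", seed=8,
        )
        steps = tw.compute_steps(tw.simulate_walker(cfg))
        waits = tw.extract_waiting_bouts(steps)
        assert len(waits) > 100


class TestRelaxationSeries:
    def test_white_noise_limit(self):
        x = tw.relaxation_series(0.0, 10**5, seed=12)
        assert x.std() == pytest.approx(1.0, abs=0.02)
        acf = tw.autocorrelation(x, max_lag=5)
        assert np.abs(acf.C[1:]).max() < 3 / np.sqrt(10**5)

    def test_ar1_autocorrelation_closed_form(self):
        x = tw.relaxation_series(0.9, 10**5, seed=12)
        acf = tw.autocorrelation(x, max_lag=20)
        taus = np.arange(1, 21)
        assert np.max(np.abs(acf.C[1:] - 0.9**taus)) < 3 / np.sqrt(10**5)

    def test_stationary_variance(self):
        x = tw.relaxation_series(0.9, 10**5, seed=13)
        assert x.var() == pytest.approx(1 / (1 - 0.81), rel=0.05)

    def test_nonstationary_rejected(self):
        with pytest.raises(ValueError):
            tw.relaxation_series(1.0, 100)


class TestSpectralNoise:
    @pytest.mark.parametrize("beta", [0.0, 1.0, 2.0])
    def test_psd_slope_round_trip(self, beta):
        x = tw.spectral_noise(beta, 65536, seed=8)
        spec = tw.power_spectrum(x, segment_length=4096)
        assert spec.beta.exponent == pytest.approx(beta, abs=0.1)

    def test_zero_mean_unit_variance(self):
        x = tw.spectral_noise(1.0, 4096, seed=3)
        assert x.mean() == pytest.approx(0.0, abs=1e-12)
        assert x.std() == pytest.approx(1.0, abs=1e-12)
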