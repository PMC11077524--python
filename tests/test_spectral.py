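"""Spectral distributions: analytic forms, fitting from trajectories,
inner/outer decomposition and reorganization-energy calibration."""

import numpy as np
import pytest

from bdan.bath import (
    AnalyticBathSpec,
    analytic_distribution,
    bath_correlation_quadrature,
    debye_grid,
    exponential_modes,
)
from bdan.constants import HBAR_EV_FS, KB_EV_K, beta_ev, cm1_to_ev
from bdan.free_energy import classical_fgr_rate
from bdan.rates import marcus_rate
from bdan.spectral import (
    calibrate_lambda,
    estimate_autocovariance,
    fit_spectral_distribution,
    decompose_reorganization,
)
from bdan.synthetic import (
    EnergyGapTrajectory,
    generate_gap_trajectory,
    generate_two_state_samples,
)

T = 298.15


class TestAnalyticDistribution:
    def test_unit_area_after_renormalisation(self, debye_density):
        assert debye_density.area == pytest.approx(1.0, abs=1e-9)

    def test_underdamped_oscillator_peaks_at_resonance(self):
        bo = AnalyticBathSpec("brownian_oscillator", lam=0.2, Omega=0.18, gamma=0.005)
        d = analytic_distribution(bo, np.linspace(1e-4, 0.6, 8000))
        assert d.omega[np.argmax(d.rho)] == pytest.approx(0.18, abs=0.002)

    def test_coarse_grained_model_total_reorganization(self):
        """The printed beta-reduced Debye+BO parameters give lam ~ 0.483 eV."""
        beta = beta_ev(T)
        de = AnalyticBathSpec("debye", lam=10.1459 / beta, omega_D=0.1831 / beta)
        bo = AnalyticBathSpec(
            "brownian_oscillator", lam=8.6780 / beta, Omega=6.76 / beta, gamma=4.0 / beta
        )
        d = analytic_distribution([de, bo], debye_grid(de.omega_D, 1.5, 6000))
        assert d.lam == pytest.approx(0.4836, abs=0.002)
        # the Brownian-oscillator frequency corresponds to ~1400 cm^-1
        assert bo.Omega * 8065.544 == pytest.approx(1400.0, rel=0.01)

    def test_truncating_grid_warns(self):
        de = AnalyticBathSpec("debye", lam=0.2, omega_D=0.05)
        with pytest.warns(UserWarning, match="mass"):
            analytic_distribution(de, np.linspace(1e-4, 0.2, 100))


class TestExponentialDecomposition:
    def test_correlation_function_rebuilt_within_1pc(self):
        """Mode sum vs direct quadrature over [2 fs, 5 hbar/Lambda]."""
        beta = beta_ev(T)
        de = AnalyticBathSpec("debye", lam=0.5 / beta, omega_D=1.0 / beta)
        bo = AnalyticBathSpec(
            "brownian_oscillator", lam=0.5 / beta, Omega=4.0 / beta, gamma=1.0 / beta
        )
        d = analytic_distribution([de, bo], debye_grid(de.omega_D, 3.2, 48000))
        ts = np.linspace(5.0, 5 * HBAR_EV_FS / (bo.gamma / 2), 25)
        Cq = bath_correlation_quadrature(d, T, ts)
        modes, _ = exponential_modes([de, bo], T, 50)
        Cm = sum(c * np.exp(-nu * ts / HBAR_EV_FS) for c, nu in modes)
        assert np.max(np.abs(Cm - Cq)) / abs(Cq[0]) < 0.01

    def test_mode_sum_carries_total_reorganization(self):
        de = AnalyticBathSpec("debye", lam=0.26, omega_D=0.0047)
        bo = AnalyticBathSpec("brownian_oscillator", lam=0.22, Omega=0.17, gamma=0.10)
        modes, _ = exponential_modes([de, bo], T, 4)
        lam = -sum((c / nu).imag for c, nu in modes)
        assert lam == pytest.approx(0.48, abs=1e-10)


class TestAutocovariance:
    def test_constant_series_gives_zero_covariance(self):
        traj = EnergyGapTrajectory(dt=1.0, values=np.full(1000, 0.7))
        lags, cov = estimate_autocovariance(traj, 100.0)
        assert np.allclose(cov, 0.0)

    def test_lag_zero_equals_sample_variance(self):
        rng = np.random.default_rng(0)
        traj = EnergyGapTrajectory(dt=1.0, values=rng.normal(size=5000))
        _, cov = estimate_autocovariance(traj, 100.0)
        assert cov[0] == pytest.approx(traj.values.var(), rel=1e-10)

    def test_overlong_lag_rejected(self):
        traj = EnergyGapTrajectory(dt=1.0, values=np.zeros(100))
        with pytest.raises(ValueError):
            estimate_autocovariance(traj, 50.0)


@pytest.fixture(scope="module")
def fitted(debye_density):
    traj = generate_gap_trajectory(
        debye_density, T, dt=1.0, n_steps=200_000, n_modes=1000, seed=7
    )
    return fit_spectral_distribution(traj, T, max_lag=150.0)


class TestSpectralFit:

    def test_round_trip_recovers_lam_within_5pc(self, fitted):
        assert fitted.lam == pytest.approx(0.24, rel=0.05)

    def test_round_trip_density_shape_l1(self, fitted, debye_density):
        r_true = np.interp(fitted.omega, debye_density.omega, debye_density.rho)
        assert np.trapezoid(np.abs(fitted.rho - r_true), fitted.omega) < 0.1

    def test_unit_area_contract(self, fitted):
        assert np.trapezoid(fitted.rho, fitted.omega) == pytest.approx(1.0, abs=1e-6)

    def test_two_independent_baths_fit_additively(self):
        """Covariance is bilinear: summed processes fit the lam-weighted density."""
        wd1, wd2 = HBAR_EV_FS / 10.0, HBAR_EV_FS / 60.0
        d1 = analytic_distribution(
            AnalyticBathSpec("debye", lam=0.15, omega_D=wd1), debye_grid(wd1, 3.0, 8192)
        )
        d2 = analytic_distribution(
            AnalyticBathSpec("debye", lam=0.15, omega_D=wd2), debye_grid(wd2, 3.0, 8192)
        )
        t1 = generate_gap_trajectory(d1, T, 1.0, 150_000, 600, seed=1)
        t2 = generate_gap_trajectory(d2, T, 1.0, 150_000, 600, seed=2)
        both = EnergyGapTrajectory(dt=1.0, values=t1.values + t2.values)
        fit = fit_spectral_distribution(both, T, max_lag=150.0)
        f1 = fit_spectral_distribution(t1, T, max_lag=150.0)
        f2 = fit_spectral_distribution(t2, T, max_lag=150.0)
        target = 0.5 * f1.rho + 0.5 * f2.rho  # lam-weighted sum of parts
        assert fit.lam == pytest.approx(0.30, rel=0.06)
        assert np.trapezoid(np.abs(fit.rho - target), fit.omega) < 0.05


@pytest.fixture(scope="module")
def split_density():
    wd_i, wd_o = HBAR_EV_FS / 8.0, HBAR_EV_FS / 50.0
    inner = analytic_distribution(
        AnalyticBathSpec("debye", lam=0.18, omega_D=wd_i), debye_grid(wd_i, 3.0, 8192)
    )
    outer = analytic_distribution(
        AnalyticBathSpec("debye", lam=0.10, omega_D=wd_o), debye_grid(wd_o, 3.0, 8192)
    )
    total = analytic_distribution(
        [
            AnalyticBathSpec("debye", lam=0.18, omega_D=wd_i),
            AnalyticBathSpec("debye", lam=0.10, omega_D=wd_o),
        ],
        debye_grid(wd_o, 3.0, 8192),
    )
    total.parts = {"inner": inner, "outer": outer}
    return total


class TestDecomposition:

    def test_independent_components_cross_term_negligible(self, split_density):
        traj = generate_gap_trajectory(split_density, T, 1.0, 150_000, 600, seed=13)
        sd = decompose_reorganization(traj, T, max_lag=150.0)
        parts = sd.meta["lam_parts"]
        assert abs(parts["cross"]) < 0.05 * parts["total"]
        assert parts["inner"] == pytest.approx(0.18, rel=0.10)
        assert parts["outer"] == pytest.approx(0.10, rel=0.10)

    def test_parts_sum_to_total(self, split_density):
        traj = generate_gap_trajectory(split_density, T, 1.0, 100_000, 400, seed=14)
        sd = decompose_reorganization(traj, T, max_lag=120.0)
        p = sd.meta["lam_parts"]
        assert p["inner"] + p["outer"] + p["cross"] == pytest.approx(p["total"], rel=0.02)

    def test_zero_environment_component(self):
        rng_vals = np.sin(np.linspace(0, 300, 20000)) * 0.1 + 0.01 * np.random.default_rng(0).standard_normal(20000)
        traj = EnergyGapTrajectory(
            dt=1.0, values=rng_vals, components=(rng_vals, np.zeros_like(rng_vals))
        )
        sd = decompose_reorganization(traj, T, max_lag=500.0)
        p = sd.meta["lam_parts"]
        assert p["outer"] == pytest.approx(0.0, abs=1e-12)
        assert p["cross"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_components_rejected(self):
        traj = EnergyGapTrajectory(dt=1.0, values=np.random.default_rng(1).normal(size=1000))
        with pytest.raises(ValueError):
            decompose_reorganization(traj, T)


class TestCalibrateLambda:
    def test_gaussian_samples_recover_variance_lambda(self):
        ss = generate_two_state_samples(-0.057, 0.550, T, 200_000, seed=21)
        lam = calibrate_lambda(T, samples=ss.samples[0])
        assert lam == pytest.approx(0.550, rel=0.01)

    def test_tilted_samples_shift_lambda_towards_tail(self):
        """An exponential tilt fattens the eps=0 tail; the resonance-matched
        lam must exceed the variance-based estimate (oracle: direct density
        arithmetic for the tilted Gaussian)."""
        lam0, dA = 0.5, -0.3
        rng = np.random.default_rng(4)
        sig2 = 2 * lam0 * KB_EV_K * T
        m = dA + lam0
        # tilt p(x) -> p(x) e^{-a x} (renormalised): still Gaussian, mean m - a sig2
        a = 3.0
        x = rng.normal(m - a * sig2, np.sqrt(sig2), 300_000)
        lam_var = x.var() / (2 * KB_EV_K * T)
        p0 = np.exp(-((0 - x.mean()) ** 2) / (2 * sig2)) / np.sqrt(2 * np.pi * sig2)
        lam_cal = calibrate_lambda(
            T, mean_gap=x.mean(), resonance_density=p0, lam_guess=lam_var
        )
        # tail at 0 fattened relative to a Gaussian with the same variance
        # whose mean moved away: calibrated lam grows
        assert lam_cal > lam_var

    def test_calibrated_lambda_reproduces_classical_rate(self):
        """Marcus with the calibrated lam equals the crossing-statistics rate."""
        ss = generate_two_state_samples(-0.057, 0.550, T, 200_000, seed=22)
        x = ss.samples[0]
        lam = calibrate_lambda(T, samples=x)
        dA_eff = x.mean() - lam
        k_marcus = marcus_rate(dA_eff, lam, 99.0, T)
        from bdan.free_energy import quadratic_extrapolation

        q = quadratic_extrapolation(x, T)
        p0 = np.exp(-q.mean**2 / (2 * q.variance)) / np.sqrt(2 * np.pi * q.variance)
        k_class = classical_fgr_rate(q.barrier, 99.0, T, resonance_density=p0)
        assert k_marcus.value == pytest.approx(k_class.value, rel=0.02)
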