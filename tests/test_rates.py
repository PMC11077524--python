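"""Nonadiabatic rate theory: cumulant lineshape exponent, Marcus, MLJ and
the full quantum golden-rule integral with its classical/vibronic limits."""

import numpy as np
import pytest

from bdan.bath import (
    AnalyticBathSpec,
    SpectralDistribution,
    analytic_distribution,
    debye_grid,
    exponential_modes,
)
from bdan.constants import HBAR_EV_FS, KB_EV_K, beta_ev, cm1_to_ev
from bdan.rates import (
    TwoStateSystem,
    apply_recrossing_correction,
    lineshape_exponent,
    marcus_rate,
    mlj_rate,
    quantum_fgr_rate,
    quantum_fgr_rate_from_modes,
)

T = 298.15


def classical_support_density(lam=0.4, w_char=0.001, w_max=0.005):
    """Compactly supported bath entirely below kB T / 5: classical limit."""
    w = np.linspace(1e-6, w_max, 2000)
    rho = 1.0 / (1.0 + (w / w_char) ** 2)
    return SpectralDistribution(w, rho / np.trapezoid(rho, w), lam=lam)


class TestLineshapeExponent:
    def test_initial_value_and_slope(self, composite_density):
        t = np.array([0.0, 1e-5, 2e-5])
        le = lineshape_exponent(composite_density, -0.5, T, "absorption", t)
        assert le.values[0] == 0.0
        slope = (le.values[1] - le.values[0]) / 1e-5
        # dG/dt(0) = -i(DeltaA + lam)/hbar
        assert slope.imag == pytest.approx(-(-0.5 + composite_density.lam) / HBAR_EV_FS, rel=1e-4)
        assert abs(slope.real) < 1e-6

    def test_short_time_gaussian_decay(self, composite_density):
        d = composite_density
        beta = beta_ev(T)
        coth = 1.0 / np.tanh(np.clip(beta * d.omega / 2, 1e-12, None))
        sig2 = d.lam * np.trapezoid(d.rho * d.omega * coth, d.omega)
        t = np.array([0.0, 0.1, 0.2])
        le = lineshape_exponent(d, -0.5, T, "absorption", t)
        for i in (1, 2):
            assert le.values[i].real == pytest.approx(
                -sig2 * t[i] ** 2 / (2 * HBAR_EV_FS**2), rel=0.02
            )

    def test_high_temperature_limit_is_classical_gaussian(self):
        d = classical_support_density()
        lamkT = d.lam * KB_EV_K * T
        t = np.array([0.0, 1.0, 2.0])
        le = lineshape_exponent(d, -0.3, T, "absorption", t)
        for i in (1, 2):
            assert le.values[i].real == pytest.approx(
                -lamkT * t[i] ** 2 / HBAR_EV_FS**2, rel=0.01
            )

    def test_real_part_never_positive(self, composite_density):
        le = lineshape_exponent(composite_density, -1.0, T, "emission",
                                np.linspace(0, 500, 2000))
        assert np.all(le.values.real <= 1e-12)


class TestMarcus:
    def test_charge_separation_printed_value(self):
        k = marcus_rate(-0.057, 0.550, 99.0, T)
        assert k.value == pytest.approx(4.8e10, rel=0.10)

    def test_charge_recombination_printed_value(self):
        k = marcus_rate(-2.397, 0.483, 1904.0, T)
        assert k.value == pytest.approx(1.1e-17, rel=1.0)

    def test_activationless_at_minus_lambda(self):
        k = marcus_rate(-0.5, 0.5, 50.0, T)
        assert k.diagnostics["activation_energy_eV"] == pytest.approx(0.0, abs=1e-15)


class TestMLJ:
    def test_zero_inner_reorganization_reduces_to_marcus(self):
        k_mlj = mlj_rate(-0.3, 0.0, 1500.0, 0.4, 80.0, T)
        k_m = marcus_rate(-0.3, 0.4, 80.0, T)
        assert k_mlj.value == pytest.approx(k_m.value, rel=1e-12)

    def test_deep_inverted_tunneling_enhancement_1e24(self):
        """50/50 reorganization split at 1500 cm^-1: ~1e24-fold enhancement."""
        k_mlj = mlj_rate(-2.397, 0.2415, 1500.0, 0.2415, 1904.0, T)
        k_m = marcus_rate(-2.397, 0.483, 1904.0, T)
        assert 23.5 < np.log10(k_mlj.value / k_m.value) < 25.5

    def test_truncated_sum_equals_exhaustive_sum(self):
        k_auto = mlj_rate(-1.5, 0.3, 1400.0, 0.3, 500.0, T)
        k_full = mlj_rate(-1.5, 0.3, 1400.0, 0.3, 500.0, T, n_max=500)
        assert k_auto.value == pytest.approx(k_full.value, rel=1e-12)


class TestQuantumFGR:
    def test_classical_bath_matches_marcus(self):
        d = classical_support_density()
        for dA in (-0.2, -0.6):
            sys = TwoStateSystem("A", "B", dA, d.lam, 0.01, T, density_A=d)
            kq = quantum_fgr_rate(sys)
            km = marcus_rate(dA, d.lam, 0.01 * 8065.544, T)
            assert kq.value == pytest.approx(km.value, rel=0.01)

    def test_classical_limit_monotone_under_frequency_scaling(self):
        """Scaling all bath frequencies to zero approaches Marcus monotonically."""
        km = marcus_rate(-0.6, 0.4, 80.0, T).value
        devs = []
        for s in (1.0, 0.5, 0.25, 0.125):
            d = classical_support_density(w_char=0.004 * s, w_max=0.02 * s)
            sys = TwoStateSystem("A", "B", -0.6, d.lam, cm1_to_ev(80.0), T, density_A=d)
            devs.append(abs(quantum_fgr_rate(sys).value / km - 1.0))
        assert all(a >= b - 1e-4 for a, b in zip(devs[:-1], devs[1:]))
        assert devs[-1] < 0.01

    def test_single_mode_plus_solvent_matches_mlj(self):
        """BO(gamma small) + slow Debye against the analytic MLJ sum."""
        W = cm1_to_ev(1500.0)
        bo = AnalyticBathSpec("brownian_oscillator", lam=0.2415, Omega=W, gamma=0.001)
        de = AnalyticBathSpec("debye", lam=0.2415, omega_D=0.0005)
        d = analytic_distribution([de, bo], debye_grid(0.0005, 0.5, 12000))
        for dA in (-2.397, -1.2, -0.4):
            sys = TwoStateSystem("A", "B", dA, d.lam, cm1_to_ev(1904.0), T, density_A=d)
            kq = quantum_fgr_rate(sys)
            km = mlj_rate(dA, 0.2415, 1500.0, 0.2415, 1904.0, T)
            assert kq.value == pytest.approx(km.value, rel=0.05)

    def test_detailed_balance(self, composite_density):
        d = composite_density
        beta = beta_ev(T)
        for dA in (-0.3, -0.8):
            kf = quantum_fgr_rate(
                TwoStateSystem("A", "B", dA, d.lam, 0.01, T, density_A=d)
            ).value
            kb = quantum_fgr_rate(
                TwoStateSystem("B", "A", -dA, d.lam, 0.01, T, density_A=d)
            ).value
            assert kf / kb == pytest.approx(np.exp(-beta * dA), rel=0.01)

    def test_grid_refinement_invariance(self, composite_density):
        sys = TwoStateSystem("A", "B", -0.8, composite_density.lam, 0.01, T,
                             density_A=composite_density)
        k = quantum_fgr_rate(sys, grid_refine_check=True)
        assert k.diagnostics["per_density"][0]["grid_refine_rel_change"] < 1e-6

    def test_a_b_density_averaging(self, composite_density, debye_density):
        d2 = debye_density.with_lam(composite_density.lam)
        sys = TwoStateSystem("A", "B", -0.5, composite_density.lam, 0.01, T,
                             density_A=composite_density, density_B=d2)
        k = quantum_fgr_rate(sys)
        comps = k.diagnostics["component_rates_s"]
        assert len(comps) == 2
        assert k.value == pytest.approx(np.mean(comps), rel=1e-12)

    def test_mode_sum_evaluation_agrees_with_contour(self):
        """Two independent evaluations of the same bath's golden-rule rate."""
        beta = beta_ev(T)
        de = AnalyticBathSpec("debye", lam=10.1459 / beta, omega_D=0.1831 / beta)
        bo = AnalyticBathSpec(
            "brownian_oscillator", lam=8.6780 / beta, Omega=6.76 / beta, gamma=4.0 / beta
        )
        modes, delta = exponential_modes([de, bo], T, 500)
        km = quantum_fgr_rate_from_modes(
            modes, de.lam + bo.lam, -2.397, cm1_to_ev(1904.0), T, tail_delta=delta
        )
        d = analytic_distribution([de, bo], debye_grid(de.omega_D, 4.5, 24000))
        sys = TwoStateSystem("A", "B", -2.397, d.lam, cm1_to_ev(1904.0), T, density_A=d)
        kg = quantum_fgr_rate(sys)
        assert km.value == pytest.approx(kg.value, rel=0.01)


class TestRecrossingCorrection:
    def test_scaling_and_provenance(self):
        base = marcus_rate(-0.5, 0.5, 100.0, T)
        corr = apply_recrossing_correction(base, 0.9)
        assert corr.value == pytest.approx(0.9 * base.value, rel=1e-14)
        corr2 = apply_recrossing_correction(corr, 1.0)
        assert corr2.value == pytest.approx(corr.value, rel=1e-14)
        assert len(corr2.diagnostics["corrections"]) == 2

    def test_bracket_of_printed_recrossing_pair(self):
        """0.9 on 3.6e7 lands between the printed with/without values."""
        from bdan.rates import RateResult

        k = apply_recrossing_correction(RateResult(3.6e7, "quantum_fgr"), 0.9)
        assert 3.2e7 < k.value < 3.6e7

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.6])
    def test_out_of_range_factor_rejected(self, bad):
        with pytest.raises(ValueError):
            apply_recrossing_correction(marcus_rate(-0.5, 0.5, 100.0, T), bad)
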