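"""MBAR/WHAM free-energy estimation, quadratic CDF extrapolation and the
classical golden-rule rates built on them."""

import numpy as np
import pytest

from bdan.constants import KB_EV_K, beta_ev
from bdan.free_energy import (
    EstimatorDegenerateError,
    classical_fgr_rate,
    linear_response_parameters,
    mbar_free_energy_curves,
    quadratic_extrapolation,
    wham_curves,
)
from bdan.synthetic import (
    GapSampleSet,
    generate_two_state_samples,
    generate_umbrella_windows,
)

T = 298.15
kT = KB_EV_K * T


class TestMBAR:
    def test_identical_states_give_zero_free_energy_change(self):
        rng = np.random.default_rng(0)
        xs = [rng.normal(0.2, 0.1, 20000) for _ in range(2)]
        us = [np.stack([(x - 0.2) ** 2 / 0.02] * 2) for x in xs]
        ss = GapSampleSet(samples=xs, reduced_energies=us, temperature=T)
        _, dA, sdA = mbar_free_energy_curves(ss, T, np.linspace(-0.2, 0.6, 60))
        assert abs(dA) < 2 * sdA + 1e-4

    def test_recovers_generator_free_energy_within_2sigma(self):
        ss = generate_two_state_samples(-0.057, 0.550, T, 50_000, seed=3)
        _, dA, sdA = mbar_free_energy_curves(ss, T, np.linspace(-1.3, 1.2, 120))
        assert abs(dA - (-0.057)) < 2 * sdA
        assert sdA < 0.01

    def test_curve_minima_separated_by_twice_lambda(self):
        ss = generate_two_state_samples(-0.1, 0.45, T, 80_000, seed=8)
        curves, _, _ = mbar_free_energy_curves(ss, T, np.linspace(-1.2, 1.1, 200))
        mins = [c.epsilon[np.nanargmin(c.a_values)] for c in curves]
        assert mins[0] - mins[1] == pytest.approx(2 * 0.45, abs=0.05)

    def test_curves_differ_by_the_gap_itself(self):
        """A_B(eps) - A_A(eps) = eps (pointwise diabatic identity)."""
        ss = generate_two_state_samples(-0.057, 0.550, T, 200_000, seed=5)
        curves, dA, _ = mbar_free_energy_curves(ss, T, np.linspace(-0.9, 0.8, 80))
        a, b = curves[0].a_values, curves[1].a_values
        ok = np.isfinite(a) & np.isfinite(b)
        resid = (b - a)[ok] - curves[0].epsilon[ok]
        assert np.max(np.abs(resid)) < 0.02

    def test_disjoint_states_raise(self):
        xs = [np.linspace(0, 1, 1000), np.linspace(5, 6, 1000)]
        us = [np.zeros((2, 1000)), np.zeros((2, 1000))]
        ss = GapSampleSet(samples=xs, reduced_energies=us, temperature=T)
        with pytest.raises(EstimatorDegenerateError):
            mbar_free_energy_curves(ss, T, np.linspace(0, 6, 50))


class TestQuadraticExtrapolation:
    def test_harmonic_barrier_closed_form(self):
        ss = generate_two_state_samples(-0.057, 0.550, T, 50_000, seed=13)
        q = quadratic_extrapolation(ss.samples[0], T)
        assert q.barrier == pytest.approx((0.493**2) / (4 * 0.550), rel=0.03)

    def test_deep_inverted_charge_recombination_barrier(self):
        """SCT->S0 harmonic parameters: barrier ~ (dA+lam)^2/4lam = 1.896 eV."""
        ss = generate_two_state_samples(-2.397, 0.483, T, 100_000, seed=17)
        q = quadratic_extrapolation(ss.samples[0], T)
        assert q.barrier == pytest.approx(1.896, rel=0.03)

    def test_agrees_with_histogram_when_samples_straddle_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.15, 0.12, 400_000)
        q = quadratic_extrapolation(x, T)
        hist, edges = np.histogram(x, bins=200, density=True)
        centers = 0.5 * (edges[1:] + edges[:-1])
        p0 = np.interp(0.0, centers, hist)
        barrier_hist = -kT * np.log(p0 / hist.max())
        assert q.barrier == pytest.approx(barrier_hist, rel=0.05)

    def test_degenerate_or_tiny_input_rejected(self):
        with pytest.raises(ValueError):
            quadratic_extrapolation(np.ones(5000), T)
        with pytest.raises(ValueError):
            quadratic_extrapolation(np.random.default_rng(0).normal(size=100), T)


class TestWHAM:
    def test_single_unbiased_window_is_log_histogram(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0.0, 0.1, 50_000)
        ss = GapSampleSet(
            samples=[x], reduced_energies=[np.zeros((1, len(x)))],
            temperature=T, bias_spec=[(0.0, 0.0)],
        )
        grid = np.linspace(-0.35, 0.35, 70)
        half = 0.5 * (grid[1] - grid[0])
        curve = wham_curves(ss, T, grid)
        hist, edges = np.histogram(x, bins=np.concatenate([
            [grid[0] - half], 0.5 * (grid[1:] + grid[:-1]), [grid[-1] + half]
        ]), density=True)
        ref = -kT * np.log(hist)
        ref -= np.nanmin(ref[hist > 0])
        ok = hist > 0
        assert np.allclose(curve.a_values[ok], ref[ok], atol=1e-8)

    def test_umbrella_barrier_matches_harmonic_closed_form(self):
        centers = np.linspace(-1.638 + 0.512, 0.0, 12)
        uw = generate_umbrella_windows(
            -1.638, 0.512, T, centers, curvature=8.0, n_per_window=20_000, seed=11
        )
        grid = np.linspace(-1.35, 0.15, 160)
        curve = wham_curves(uw, T, grid)
        barrier = np.interp(0.0, curve.epsilon, curve.a_values) - np.nanmin(curve.a_values)
        assert barrier == pytest.approx(0.619, rel=0.03)

    def test_wham_and_mbar_agree_pointwise(self):
        centers = np.linspace(-0.5, 0.3, 8)
        uw = generate_umbrella_windows(
            -0.4, 0.25, T, centers, curvature=4.0, n_per_window=30_000, seed=4
        )
        grid = np.linspace(-0.55, 0.35, 90)
        wc = wham_curves(uw, T, grid)
        curves, _, _ = mbar_free_energy_curves(uw, T, grid, min_effective=50)
        # MBAR curve for the (unbiased part of) window 0 differs from the
        # unbiased curve by that window's bias; compare through densities of
        # the first window then strip the bias analytically instead: use the
        # unbiased WHAM curve vs MBAR-reweighted unbiased state by appending
        # the unbiased state's reduced energies.
        beta = beta_ev(T)
        xs = uw.samples
        us = []
        for k, x in enumerate(xs):
            u_bias = uw.reduced_energies[k]
            u_unb = beta * (x - (-0.4 + 0.25)) ** 2 / (4 * 0.25)
            us.append(np.vstack([u_bias, u_unb[None, :]]))
        # no samples from the unbiased state itself: give it an empty row by
        # reusing window samples (MBAR handles zero-sample states via N_k=0
        # only awkwardly), so instead reweight: build a sample set whose
        # "states" are windows plus target and sample counts stay with the
        # windows; simplest check: compare curve shapes where both defined.
        a_w = wc.a_values - np.nanmin(wc.a_values)
        m0 = curves[0]
        bias0 = 0.5 * 4.0 * (grid - centers[0]) ** 2
        a_m = m0.a_values - bias0
        a_m -= np.nanmin(a_m[np.isfinite(a_m)])
        ok = np.isfinite(a_w) & np.isfinite(a_m)
        assert np.nanmax(np.abs(a_w[ok] - a_m[ok])) < 0.01 + 0.01 * np.nanmax(a_w[ok])


class TestClassicalRates:
    def test_charge_separation_rate_matches_printed_value(self, params):
        row = params.lookup("SBD", "SCT")
        barrier = (row.delta_A + row.lam) ** 2 / (4 * row.lam)
        k = classical_fgr_rate(barrier, row.coupling_cm1, T, lam=row.lam)
        assert k.value == pytest.approx(4.8e10, rel=0.10)

    def test_charge_recombination_rate_order_of_magnitude(self, params):
        row = params.lookup("SCT", "S0")
        barrier = (row.delta_A + row.lam) ** 2 / (4 * row.lam)
        k = classical_fgr_rate(barrier, row.coupling_cm1, T, lam=row.lam)
        assert k.value == pytest.approx(1.1e-17, rel=1.0)  # printed-lambda precision

    def test_activationless_prefactor_limit(self):
        k = classical_fgr_rate(0.0, 100.0, T, lam=0.5)
        from bdan.constants import HBAR_EV_FS, cm1_to_ev

        H = cm1_to_ev(100.0)
        expected = (2 * np.pi / HBAR_EV_FS) * H**2 / np.sqrt(4 * np.pi * 0.5 * kT) * 1e15
        assert k.value == pytest.approx(expected, rel=1e-12)

    def test_linear_response_inversion(self):
        lr = linear_response_parameters(0.493, -0.607)
        assert lr["lam"] == pytest.approx(0.550)
        assert lr["delta_A"] == pytest.approx(-0.057)
        assert linear_response_parameters(0.1, 0.1)["degenerate"]

    def test_linear_response_matches_mbar_on_synthetic_samples(self):
        ss = generate_two_state_samples(-0.3, 0.5, T, 100_000, seed=6)
        lr = linear_response_parameters(ss.samples[0].mean(), ss.samples[1].mean())
        _, dA, sdA = mbar_free_energy_curves(ss, T, np.linspace(-1.4, 1.2, 100))
        assert lr["lam"] == pytest.approx(0.5, abs=0.01)
        assert abs(lr["delta_A"] - dA) < 3 * sdA + 0.005
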