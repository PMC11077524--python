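"""Spectral distributions from energy-gap trajectories.

The spin-boson mapping takes its bath *shape* from the tapered cosine
transform of the classical autocovariance of the gap fluctuations, clipped
at zero and renormalised to unit area; the reorganization energy carries all
scale and is set either from the linear-response variance ``sigma^2 =
2 lam kB T`` or by calibration against the classical resonance statistics
(``calibrate_lambda``).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .bath import SpectralDistribution
from .constants import HBAR_EV_FS, beta_ev
from .free_energy import quadratic_extrapolation
from .synthetic import EnergyGapTrajectory, GapSampleSet

DEFAULT_OMEGA_MAX = 0.75  # eV, ~6050 cm^-1: covers the aromatic C=C stretches
DEFAULT_N_OMEGA = 4096


class SpectralFitError(RuntimeError):
    """The transform was unusable (drifting input or negative-dominated)."""


def estimate_autocovariance(
    traj: EnergyGapTrajectory, max_lag: float, values: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Unbiased stationary autocovariance of the gap fluctuations.

    Returns ``(lags_fs, cov_eV2)`` up to ``max_lag``; the lag-0 entry is the
    (biased-denominator) sample variance, each lag-k entry is normalised by
    ``N - k``.  ``values`` overrides the trajectory's own series (used for
    the molecular/environment components).
    """
    x = traj.values if values is None else np.asarray(values, dtype=float)
    n = len(x)
    n_lag = int(np.floor(max_lag / traj.dt)) + 1
    if n_lag > n // 5 + 1:
        raise ValueError(
            f"max_lag {max_lag} fs exceeds a fifth of the trajectory length"
        )
    dx = x - x.mean()
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(dx, nfft)
    acf = np.fft.irfft(f * np.conj(f), nfft)[:n_lag]
    acf /= n - np.arange(n_lag)
    acf *= n / (n - 0.0)  # lag-0 equals the sample variance by construction
    return traj.dt * np.arange(n_lag), acf


def _cross_covariance(x, y, dt, n_lag):
    """Symmetrised stationary cross-covariance of two series."""
    n = len(x)
    dx, dy = x - x.mean(), y - y.mean()
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fx, fy = np.fft.rfft(dx, nfft), np.fft.rfft(dy, nfft)
    cxy = np.fft.irfft(fx * np.conj(fy), nfft)[:n_lag]
    cyx = np.fft.irfft(fy * np.conj(fx), nfft)[:n_lag]
    return 0.5 * (cxy + cyx) / (n - np.arange(n_lag))


def _check_stationary(x: np.ndarray):
    """Reject drifting series: the half-means must agree within 3 sigma."""
    n = len(x)
    blocks = np.array_split(x, 10)
    bm = np.array([b.mean() for b in blocks])
    se_half = bm.std(ddof=1) * np.sqrt(2.0 / 5.0)
    drift = abs(x[: n // 2].mean() - x[n // 2 :].mean())
    if se_half > 0 and drift > 3.0 * se_half:
        raise SpectralFitError(
            f"trajectory drifts: half-mean difference {drift:.3g} eV exceeds "
            f"3 sigma ({3 * se_half:.3g} eV)"
        )


def _cosine_transform(lags, cov, omega, window: str):
    """Tapered cosine transform of an autocovariance onto a frequency grid."""
    if window == "hann":
        taper = 0.5 * (1.0 + np.cos(np.pi * np.arange(len(lags)) / (len(lags) - 1)))
    elif window in ("none", "boxcar"):
        taper = np.ones(len(lags))
    else:
        raise ValueError(f"unknown window {window!r}")
    c = cov * taper
    ph = np.outer(omega, lags) / HBAR_EV_FS
    return np.trapezoid(np.cos(ph) * c[None, :], lags, axis=1)


def fit_spectral_distribution(
    traj: EnergyGapTrajectory,
    temperature: float,
    window: str = "hann",
    lam_override: float | None = None,
    max_lag: float | None = None,
    omega_grid: np.ndarray | None = None,
) -> SpectralDistribution:
    """Fit rho(omega) from a gap trajectory.

    Shape from the tapered cosine transform of the autocovariance of
    ``deltaDeltaV``, negative leakage clipped to zero, renormalised; ``lam``
    from the classical variance ``sigma^2/(2 kB T)`` unless overridden.  The
    clipped-mass fraction is reported in ``meta``.
    """
    _check_stationary(traj.values)
    if max_lag is None:
        max_lag = traj.dt * traj.n_steps / 5.0
    if omega_grid is None:
        omega_grid = np.linspace(0.0, DEFAULT_OMEGA_MAX, DEFAULT_N_OMEGA)
    lags, cov = estimate_autocovariance(traj, max_lag)
    raw = _cosine_transform(lags, cov, omega_grid, window)
    clipped = np.clip(raw, 0.0, None)
    pos = np.trapezoid(clipped, omega_grid)
    neg = -np.trapezoid(np.minimum(raw, 0.0), omega_grid)
    if pos <= 0 or neg > pos:
        raise SpectralFitError(
            f"cosine transform negative-dominated (pos={pos:.3g}, neg={neg:.3g});"
            " the trajectory is too short or badly sampled"
        )
    lam = cov[0] / (2.0 / beta_ev(temperature)) if lam_override is None else lam_override
    if lam <= 0:
        raise SpectralFitError("non-positive reorganization energy estimate")
    sd = SpectralDistribution(
        omega=omega_grid,
        rho=clipped / pos,
        lam=float(lam),
        provenance="fitted",
        meta={"clipped_mass_fraction": float(neg / (pos + neg)), "window": window},
    )
    return sd


def decompose_reorganization(
    traj: EnergyGapTrajectory,
    temperature: float,
    window: str = "hann",
    max_lag: float | None = None,
    omega_grid: np.ndarray | None = None,
    outer_scale: float = 1.0,
) -> SpectralDistribution:
    """Inner/outer/cross decomposition of the fitted spectral distribution.

    Inner from the molecular component's autocovariance, outer from the
    environment component's, cross from the symmetrised cross-covariance;
    the three lam contributions sum (bilinearity of the covariance) to the
    undecomposed lam.  ``outer_scale`` multiplies the outer-sphere lam (and
    covariance) before totals are formed, accommodating an outer part that
    must be rescaled to match a different solvent model.
    """
    if traj.components is None:
        raise ValueError("trajectory carries no molecular/environment components")
    mol, env = traj.components
    _check_stationary(traj.values)
    if max_lag is None:
        max_lag = traj.dt * traj.n_steps / 5.0
    if omega_grid is None:
        omega_grid = np.linspace(0.0, DEFAULT_OMEGA_MAX, DEFAULT_N_OMEGA)
    beta = beta_ev(temperature)
    n_lag = int(np.floor(max_lag / traj.dt)) + 1
    lags = traj.dt * np.arange(n_lag)

    def part(series_cov, name):
        raw = _cosine_transform(lags, series_cov, omega_grid, window)
        lam_p = series_cov[0] * beta / 2.0
        return raw, lam_p

    _, cov_mol = estimate_autocovariance(traj, max_lag, values=mol)
    _, cov_env = estimate_autocovariance(traj, max_lag, values=env)
    cov_env = cov_env * outer_scale
    cov_cross = 2.0 * _cross_covariance(mol, env, traj.dt, n_lag) * np.sqrt(outer_scale)
    raw_i, lam_i = part(cov_mol, "inner")
    raw_o, lam_o = part(cov_env, "outer")
    raw_x, lam_x = part(cov_cross, "cross")
    total_cov = cov_mol + cov_env + cov_cross
    raw_t = _cosine_transform(lags, total_cov, omega_grid, window)
    lam_t = total_cov[0] * beta / 2.0

    def to_sd(raw, lam_p, prov):
        clipped = np.clip(raw, 0.0, None)
        area = np.trapezoid(clipped, omega_grid)
        return SpectralDistribution(
            omega=omega_grid, rho=clipped / area, lam=float(max(lam_p, 1e-12)),
            provenance=prov,
        )

    sd = to_sd(raw_t, lam_t, "fitted")
    sd.parts = {
        "inner": to_sd(raw_i, lam_i, "fitted"),
        "outer": to_sd(raw_o, lam_o, "fitted"),
        "cross": {"lam": float(lam_x), "omega": omega_grid, "rho": raw_x},
    }
    sd.meta["lam_parts"] = {"inner": float(lam_i), "outer": float(lam_o),
                            "cross": float(lam_x), "total": float(lam_t)}
    return sd


class CalibrationError(RuntimeError):
    pass


def calibrate_lambda(
    temperature: float,
    mean_gap: float | None = None,
    resonance_density: float | None = None,
    samples: np.ndarray | GapSampleSet | None = None,
    lam_guess: float | None = None,
    lam_max: float = 10.0,
) -> float:
    """Reorganization energy from classical crossing statistics.

    Finds the ``lam`` for which a Gaussian with the observed mean gap and
    linear-response variance ``2 lam kB T`` reproduces the classical
    resonance density ``p(eps=0)``:

        p(0) = exp(-m^2/(4 lam kB T)) / sqrt(4 pi lam kB T).

    Either pass ``mean_gap`` and ``resonance_density`` directly, or pass
    state-A ``samples`` from which the mean is taken and ``p(0)`` is
    estimated by the quadratic-CDF extrapolation.  When the equation has two
    roots the one nearest the variance-based estimate (``lam_guess``,
    defaulting to ``var/2 kB T`` of the samples) is returned.
    """
    beta = beta_ev(temperature)
    if samples is not None:
        x = samples.samples[0] if isinstance(samples, GapSampleSet) else np.asarray(samples)
        fit = quadratic_extrapolation(x, temperature)
        mean_gap = fit.mean
        resonance_density = float(
            np.exp(-fit.mean**2 / (2.0 * fit.variance))
            / np.sqrt(2.0 * np.pi * fit.variance)
        )
        if lam_guess is None:
            lam_guess = float(np.var(x) * beta / 2.0)
    if mean_gap is None or resonance_density is None or resonance_density <= 0:
        raise ValueError("need mean_gap and a positive resonance_density (or samples)")

    def f(lam):
        return (
            -beta * mean_gap**2 / (4.0 * lam)
            - 0.5 * np.log(4.0 * np.pi * lam / beta)
            - np.log(resonance_density)
        )

    grid = np.geomspace(1e-4, lam_max, 600)
    vals = np.array([f(g) for g in grid])
    roots = []
    for i in range(len(grid) - 1):
        if np.sign(vals[i]) != np.sign(vals[i + 1]):
            roots.append(brentq(f, grid[i], grid[i + 1], xtol=1e-12))
    if not roots:
        raise CalibrationError(
            "no Gaussian reorganization energy in (0, {:.1f}] eV reproduces "
            "p(0) = {:.3g} 1/eV".format(lam_max, resonance_density)
        )
    if lam_guess is None:
        return float(min(roots))
    return float(min(roots, key=lambda r: abs(r - lam_guess)))
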