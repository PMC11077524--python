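"""Absorption/fluorescence lineshapes and radiative rates.

Spectra follow from the Fourier transform of the cumulant correlation
function c_AB(t) = exp[G(t)] of the spin-boson mapping: the unit-area
absorption lineshape of a transition with free energy change ``DeltaA``
peaks near the mean vertical gap ``DeltaA + lam`` (A-surface dynamics), the
emission lineshape near ``DeltaA - lam`` (B-surface dynamics), and the two
are mirror images about ``DeltaA``.  A rigid frequency shift accounts for a
global excited-state energy offset.  The vacuum radiative rate is obtained
from the emission lineshape's third frequency moment,

    k_r = (4/3) alpha^3 <(E/E_h)^3> mu^2 / t_au,

with mu^2 in atomic units and no refractive-index correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bath import SpectralDistribution
from .constants import (
    ATOMIC_TIME_S,
    FINE_STRUCTURE,
    HBAR_EV_FS,
    HARTREE_EV,
    beta_ev,
    cm1_to_ev,
)
from .rates import RateResult, TwoStateSystem, lineshape_exponent


class ResolutionWarning(UserWarning):
    pass


@dataclass
class Spectrum:
    """Unit-area spectral density on an energy grid (eV)."""

    omega: np.ndarray
    intensity: np.ndarray
    kind: str  # "absorption" | "fluorescence"
    labels: list[str] = field(default_factory=list)
    weights: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.intensity < -1e-12):
            raise ValueError("spectral intensity must be non-negative")
        self.intensity = np.clip(self.intensity, 0.0, None)

    @property
    def area(self) -> float:
        return float(np.trapezoid(self.intensity, self.omega))

    def moment(self, order: int = 1) -> float:
        return float(np.trapezoid(self.omega**order * self.intensity, self.omega) / self.area)

    def peak(self) -> float:
        return float(self.omega[np.argmax(self.intensity)])

    def broadened(self, sigma_cm1: float = 50.0) -> "Spectrum":
        """Gaussian instrument broadening (post-process convolution)."""
        sig = cm1_to_ev(sigma_cm1)
        dE = self.omega[1] - self.omega[0]
        half = int(np.ceil(5 * sig / dE))
        kern = np.exp(-0.5 * ((np.arange(-half, half + 1) * dE) / sig) ** 2)
        kern /= kern.sum()
        return Spectrum(
            omega=self.omega,
            intensity=np.convolve(self.intensity, kern, mode="same"),
            kind=self.kind, labels=self.labels, weights=self.weights,
        )


@dataclass
class EmissionWeights:
    """Equilibrium emission weights of the SBD*/SCT pre-equilibrium.

    Populations from ``K_CS = exp(-beta DeltaA_CS)``; the spectral weights
    are ``p_state * mu^2_state``, renormalised.
    """

    mu_squared: dict[str, float]
    delta_A_CS: float
    temperature: float

    @property
    def populations(self) -> dict[str, float]:
        K = np.exp(-beta_ev(self.temperature) * self.delta_A_CS)
        p_ct = K / (1.0 + K)
        return {"SBD": 1.0 - p_ct, "SCT": p_ct}

    def spectral_weights(self) -> dict[str, float]:
        p = self.populations
        raw = {s: p[s] * self.mu_squared[s] for s in p if s in self.mu_squared}
        tot = sum(raw.values())
        return {s: v / tot for s, v in raw.items()}


def lineshape_spectrum(
    system: TwoStateSystem,
    direction: str = "absorption",
    shift_cm1: float = 0.0,
    energy_grid: np.ndarray | None = None,
    time_grid: np.ndarray | None = None,
) -> Spectrum:
    """Unit-area lineshape of one transition from its cumulant exponent.

    The Fourier transform L(E) = (1/pi hbar) Re Int_0^inf e^{iEt/hbar}
    e^{G(t)} dt is evaluated by direct quadrature on a time grid that runs
    until |e^{G}| has decayed (or a resolution warning is emitted); the
    rigid ``shift`` is applied to the energy axis afterwards.
    """
    density = system.density_A if direction == "absorption" else (
        system.density_B or system.density_A
    )
    if time_grid is None:
        w_max = density.omega[-1]
        dt = 2.0 * np.pi * HBAR_EV_FS / w_max / 20.0
        time_grid = np.arange(0.0, 4000.0 * dt, dt)
    G = lineshape_exponent(
        density, system.delta_A, system.temperature, direction, time_grid
    )
    c = np.exp(G.values)
    if abs(c[-1]) > 1e-6:
        warnings.warn(
            f"correlation function only decayed to {abs(c[-1]):.2e}; "
            "lineshape features may be unresolved — extend the time grid",
            ResolutionWarning,
            stacklevel=2,
        )
    shift = cm1_to_ev(shift_cm1)
    center = system.delta_A + (density.lam if direction == "absorption" else -density.lam)
    if energy_grid is None:
        beta = beta_ev(system.temperature)
        coth = 1.0 / np.tanh(np.clip(beta * density.omega / 2.0, 1e-12, None))
        sig2 = density.lam * np.trapezoid(
            density.rho * density.omega * coth, density.omega
        )
        half = max(6.0 * np.sqrt(sig2), 0.5)
        energy_grid = np.linspace(center - half, center + half, 3000) + shift
    E = np.asarray(energy_grid, dtype=float)
    ph = np.outer(E - shift, G.time) / HBAR_EV_FS
    L = np.trapezoid((np.exp(1.0j * ph) * c[None, :]).real, G.time, axis=1) / (
        np.pi * HBAR_EV_FS
    )
    L = np.clip(L, 0.0, None)
    area = np.trapezoid(L, E)
    if area <= 0:
        raise RuntimeError("lineshape collapsed to zero on the requested grid")
    return Spectrum(
        omega=E, intensity=L / area, kind=(
            "absorption" if direction == "absorption" else "fluorescence"
        ),
        labels=[f"{system.label_A}->{system.label_B}"], weights=[1.0],
    )


def composite_fluorescence(
    spectra: dict[str, Spectrum], weights: EmissionWeights
) -> Spectrum:
    """Population- and dipole-weighted sum of per-state emission spectra."""
    w = weights.spectral_weights()
    states = list(spectra)
    grid = spectra[states[0]].omega
    for s in states[1:]:
        if spectra[s].omega.shape != grid.shape or not np.allclose(spectra[s].omega, grid):
            raise ValueError("component spectra must share one energy grid")
    total = np.zeros_like(grid)
    used = []
    for s in states:
        if s not in w:
            raise ValueError(f"no emission weight available for state {s!r}")
        total += w[s] * spectra[s].intensity / spectra[s].area
        used.append(w[s])
    area = np.trapezoid(total, grid)
    return Spectrum(
        omega=grid, intensity=total / area, kind="fluorescence",
        labels=states, weights=used,
    )


def radiative_rate(spectrum: Spectrum, mu_squared: float) -> RateResult:
    """Vacuum spontaneous-emission rate from a fluorescence lineshape.

    Linear in mu^2 (atomic units) and proportional to the third moment of
    the emission energy; invariant under renormalisation of the spectrum.
    """
    if spectrum.kind != "fluorescence":
        raise ValueError("radiative rate requires a fluorescence spectrum")
    if mu_squared < 0:
        raise ValueError("mu_squared must be non-negative")
    mean_E3 = spectrum.moment(3)
    k_au = (4.0 / 3.0) * FINE_STRUCTURE**3 * (mean_E3 / HARTREE_EV**3) * mu_squared
    return RateResult(
        value=float(k_au / ATOMIC_TIME_S),
        method="radiative",
        diagnostics={"mean_E3_eV3": mean_E3, "mu_squared_au": mu_squared},
    )
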