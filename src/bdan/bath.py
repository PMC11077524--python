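"""Harmonic-bath descriptions: spectral distributions and analytic baths.

A two-state electronic process coupled linearly to harmonic nuclear motion is
fully characterised by a reorganization energy ``lam`` and a unit-normalised
spectral distribution ``rho(omega)`` of the bath frequencies.  The
conventional spectral density is ``J(omega) = pi * lam * omega * rho(omega)``
so that ``(1/pi) * int J/omega domega = lam``.

Two analytic families are supported, an overdamped Debye bath

    rho_D(omega) ∝ 1 / (1 + (omega/omega_D)^2)

and an underdamped Brownian oscillator

    rho_BO(omega) ∝ gamma Omega^2 / ((omega^2 - Omega^2)^2 + gamma^2 omega^2)

whose printed prefactor conventions are shape-only: every distribution is
renormalised to unit area on its grid and ``lam`` carries all scale.  Both
families have bath correlation functions that are finite sums of decaying
exponentials, which is what the HEOM module requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import HBAR_EV_FS, beta_ev


class BathGridWarning(UserWarning):
    """Frequency grid truncates a non-negligible part of the analytic mass."""


@dataclass
class SpectralDistribution:
    """Unit-area frequency density of a harmonic bath plus its scale ``lam``.

    Parameters
    ----------
    omega:
        Ascending, non-negative frequency grid in eV (energy quanta).
    rho:
        Density values in 1/eV; normalised so that ``trapz(rho, omega) = 1``.
    lam:
        Reorganization energy in eV; carries all of the coupling scale.
    parts:
        Optional inner/outer/cross decomposition; each value is a
        ``SpectralDistribution`` (cross may have negative density).
    provenance:
        "fitted" (from a trajectory) or "analytic".
    """

    omega: np.ndarray
    rho: np.ndarray
    lam: float
    parts: dict | None = None
    provenance: str = "analytic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.omega.ndim != 1 or self.omega.shape != self.rho.shape:
            raise ValueError("omega and rho must be 1-d arrays of equal length")
        if np.any(np.diff(self.omega) <= 0) or self.omega[0] < 0:
            raise ValueError("omega grid must be ascending and non-negative")
        if not np.isfinite(self.lam) or self.lam <= 0:
            raise ValueError(f"lam must be positive, got {self.lam}")

    @property
    def area(self) -> float:
        return float(np.trapezoid(self.rho, self.omega))

    def normalized(self) -> "SpectralDistribution":
        return replace(self, rho=self.rho / self.area)

    def classical_variance(self, temperature: float) -> float:
        """Linear-response gap variance 2 lam kB T (eV^2)."""
        return 2.0 * self.lam / beta_ev(temperature)

    def with_lam(self, lam: float) -> "SpectralDistribution":
        return replace(self, lam=lam)


@dataclass(frozen=True)
class AnalyticBathSpec:
    """Parameters of one analytic bath component.

    kind="debye": overdamped solvent bath, ``omega_D`` in eV (equivalently a
    relaxation time ``tau_D = hbar/omega_D`` fs); optional metadata records a
    solvent-derived origin ``tau_D = (eps_inf/eps_r) tau_rel``.

    kind="brownian_oscillator": underdamped mode, frequency ``Omega`` and
    damping ``gamma`` (both eV).
    """

    kind: str
    lam: float
    omega_D: float | None = None
    Omega: float | None = None
    gamma: float | None = None
    meta: dict | None = None

    def __post_init__(self):
        if self.kind not in ("debye", "brownian_oscillator"):
            raise ValueError(f"unknown bath kind {self.kind!r}")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.kind == "debye":
            if self.omega_D is None or self.omega_D <= 0:
                raise ValueError("debye bath needs omega_D > 0")
        else:
            if (
                self.Omega is None
                or self.gamma is None
                or self.Omega <= 0
                or self.gamma <= 0
            ):
                raise ValueError("brownian oscillator needs Omega > 0, gamma > 0")

    @property
    def tau_D_fs(self) -> float:
        if self.kind != "debye":
            raise AttributeError("tau_D only defined for a Debye bath")
        return HBAR_EV_FS / self.omega_D

    def shape(self, omega: np.ndarray) -> np.ndarray:
        """Un-normalised density shape on a (possibly complex) grid."""
        omega = np.asarray(omega)
        if self.kind == "debye":
            return 1.0 / (1.0 + (omega / self.omega_D) ** 2)
        g, W = self.gamma, self.Omega
        return g * W**2 / ((omega**2 - W**2) ** 2 + g**2 * omega**2)

    def spectral_density(self, omega):
        """J(omega) = pi lam omega rho(omega) with the exact normalisation.

        Closed forms: Debye J = 2 lam omega_D omega / (omega^2 + omega_D^2);
        BO J = 2 lam gamma Omega^2 omega / ((omega^2-Omega^2)^2 +
        gamma^2 omega^2).  Valid for complex omega (used for Matsubara terms).
        """
        omega = np.asarray(omega)
        if self.kind == "debye":
            return 2.0 * self.lam * self.omega_D * omega / (omega**2 + self.omega_D**2)
        g, W = self.gamma, self.Omega
        return (
            2.0
            * self.lam
            * g
            * W**2
            * omega
            / ((omega**2 - W**2) ** 2 + g**2 * omega**2)
        )

    def resonant_modes(self, temperature: float) -> list[tuple[complex, complex]]:
        """Exponential modes (c_j, nu_j) from the poles of J(omega).

        The bath correlation function C(t>0) = sum_j c_j exp(-nu_j t / hbar)
        with c_j in eV^2 and Re nu_j > 0 in eV; this method returns the
        contributions of the spectral-density poles (the coth poles are
        returned by :func:`matsubara_modes`).
        """
        beta = beta_ev(temperature)
        if self.kind == "debye":
            wd = self.omega_D
            c = self.lam * wd * (1.0 / np.tan(beta * wd / 2.0) - 1.0j)
            return [(c, complex(wd))]
        Lam = self.gamma / 2.0
        if Lam >= self.Omega:
            raise ValueError("overdamped Brownian oscillator not supported")
        Wp = np.sqrt(self.Omega**2 - Lam**2)
        poles = [Wp - 1.0j * Lam, -Wp - 1.0j * Lam]
        all_roots = [Wp - 1.0j * Lam, -Wp - 1.0j * Lam, Wp + 1.0j * Lam, -Wp + 1.0j * Lam]
        modes = []
        num = 2.0 * self.lam * self.gamma * self.Omega**2
        for p in poles:
            denom = np.prod([p - q for q in all_roots if abs(q - p) > 1e-300])
            res = num * p / denom
            c = -1.0j * res * (1.0 / np.tanh(beta * p / 2.0) + 1.0)
            modes.append((complex(c), 1.0j * p))
        return modes

    def matsubara_mode(self, k: int, temperature: float) -> tuple[float, float]:
        """k-th Matsubara term: c_k exp(-nu_k t/hbar), nu_k = 2 pi k / beta."""
        beta = beta_ev(temperature)
        nu = 2.0 * np.pi * k / beta
        c = (-1.0j * (2.0 / beta) * self.spectral_density(-1.0j * nu)).real
        return c, nu


def exponential_modes(
    baths: list[AnalyticBathSpec], temperature: float, n_matsubara: int
) -> tuple[list[tuple[complex, complex]], float]:
    """Exponential decomposition of the total bath correlation function.

    Returns ``(modes, delta)`` where ``modes`` is a list of (c_j, nu_j) with
    the resonant terms of every bath plus ``n_matsubara`` shared Matsubara
    terms, and ``delta = sum_{k>K} c_k hbar / nu_k`` (eV^2 fs) is the
    Markovian weight of the truncated Matsubara tail, summed until converged.
    """
    modes = []
    for b in baths:
        modes.extend(b.resonant_modes(temperature))
    for k in range(1, n_matsubara + 1):
        c_tot = 0.0
        nu = None
        for b in baths:
            c, nu = b.matsubara_mode(k, temperature)
            c_tot += c
        modes.append((complex(c_tot), complex(nu)))
    # Markovian tail: sum_{k>K} c_k hbar / nu_k, vectorised (terms ~ 1/k^2).
    beta = beta_ev(temperature)
    ks = np.arange(n_matsubara + 1, 1_000_001)
    nus = 2.0 * np.pi * ks / beta
    c_tail = np.zeros_like(nus)
    for b in baths:
        c_tail += (-1.0j * (2.0 / beta) * b.spectral_density(-1.0j * nus)).real
    delta = float(np.sum(c_tail * HBAR_EV_FS / nus))
    return modes, delta


def bath_correlation_quadrature(
    density: SpectralDistribution, temperature: float, t_fs: np.ndarray
) -> np.ndarray:
    """C(t) = (1/pi) int J(w) [coth(beta w/2) cos(wt/hbar) - i sin(wt/hbar)] dw.

    Direct quadrature on the density grid; serves as the independent oracle
    for the exponential decompositions.
    """
    beta = beta_ev(temperature)
    w = density.omega
    J = np.pi * density.lam * w * density.rho
    t = np.asarray(t_fs, dtype=float)[:, None]
    ph = w[None, :] * t / HBAR_EV_FS
    with np.errstate(divide="ignore", invalid="ignore"):
        coth = 1.0 / np.tanh(beta * w / 2.0)
    coth = np.where(w > 0, coth, 0.0)
    integ = J[None, :] * (coth[None, :] * np.cos(ph) - 1.0j * np.sin(ph))
    if w[0] == 0.0:
        # finite w -> 0 limit: J*coth -> 2 pi lam rho(0) / beta, J*sin -> 0
        integ[:, 0] = (2.0 / beta) * np.pi * density.lam * density.rho[0]
    return np.trapezoid(integ, w, axis=1) / np.pi


def analytic_distribution(
    spec: AnalyticBathSpec | list[AnalyticBathSpec],
    omega_grid: np.ndarray,
    mass_tolerance: float = 1e-3,
) -> SpectralDistribution:
    """Tabulate one or several analytic baths on a grid, unit-normalised.

    For a list of baths the shapes are combined with weights proportional to
    their reorganization energies and ``lam`` is the sum, so that the
    composite ``J`` is the sum of the members' spectral densities.
    """
    specs = [spec] if isinstance(spec, AnalyticBathSpec) else list(spec)
    omega = np.asarray(omega_grid, dtype=float)
    if omega.ndim != 1 or len(omega) < 16:
        raise ValueError("omega_grid must be a 1-d grid with >= 16 points")
    total_lam = sum(b.lam for b in specs)
    rho = np.zeros_like(omega)
    for b in specs:
        shape = b.shape(omega)
        # normalise each component exactly using the analytic area
        if b.kind == "debye":
            area = (np.pi / 2.0) * b.omega_D
        else:
            area = np.pi / 2.0  # int g W^2/((w^2-W^2)^2+g^2 w^2) dw = pi/(2 g W^2) * g W^2
        rho += (b.lam / total_lam) * shape / area
    covered = np.trapezoid(rho, omega)
    if covered < 1.0 - mass_tolerance:
        warnings.warn(
            f"frequency grid covers only {100 * covered:.2f}% of the analytic "
            "bath mass; extend the grid",
            BathGridWarning,
            stacklevel=2,
        )
    out = SpectralDistribution(
        omega=omega, rho=rho, lam=total_lam, provenance="analytic"
    )
    return out.normalized()


def debye_grid(omega_D: float, omega_max: float, n: int = 4096) -> np.ndarray:
    """Grid resolving a Debye bath: log-spaced below, linear above omega_D."""
    lo = np.geomspace(omega_D * 1e-4, omega_D * 10.0, n // 2, endpoint=False)
    hi = np.linspace(omega_D * 10.0, omega_max, n - n // 2)
    return np.concatenate([lo, hi])
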