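"""Synthetic generators for every input the analysis assumes.

The downstream estimators (spectral-density fitting, MBAR/WHAM, rate
theories) were designed for molecular-dynamics energy-gap data.  This module
replaces those inputs with exactly solvable surrogates:

* stationary Gaussian energy-gap fluctuations with a prescribed spectral
  distribution and linear-response variance ``2 lam kB T``,
* two-state shifted-harmonic gap samples with prescribed ``Delta A`` and
  ``lam`` (gap means ``Delta A +/- lam``),
* harmonically biased (umbrella) windows along the gap coordinate,
* the transcribed BD-An parameter fixture (free energies, reorganization
  energies, couplings, dipoles, reference rates).

All generators are pure functions of their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .bath import SpectralDistribution
from .constants import HBAR_EV_FS, beta_ev


@dataclass
class EnergyGapTrajectory:
    """Uniformly sampled energy-gap series ``DeltaV(t) = V_B - V_A`` (eV).

    ``components``, when present, is a pair ``(dv_mol, dv_env)`` whose sum
    reproduces ``values`` elementwise (molecular vs environment split of the
    gap).
    """

    dt: float
    values: np.ndarray
    state_label: str = "A"
    components: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("gap values must be finite")
        if self.components is not None:
            mol, env = (np.asarray(c, dtype=float) for c in self.components)
            if mol.shape != self.values.shape or env.shape != self.values.shape:
                raise ValueError("component arrays must match values in shape")
            if np.max(np.abs(mol + env - self.values)) > 1e-10:
                raise ValueError("components must sum to values within 1e-10 eV")
            self.components = (mol, env)

    @property
    def n_steps(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.n_steps)


@dataclass
class GapSampleSet:
    """Gap samples from several thermodynamic states plus reduced energies.

    ``reduced_energies[k]`` has shape ``(n_states, N_k)``: row ``j`` is the
    dimensionless energy of the samples drawn in state ``k`` evaluated under
    state ``j``.  ``bias_spec[k] = (center_eV, curvature_eV_per_eV2)`` when
    the states are harmonically biased umbrella windows.
    """

    samples: list[np.ndarray]
    reduced_energies: list[np.ndarray]
    temperature: float
    bias_spec: list[tuple[float, float]] | None = None
    labels: list[str] | None = None

    def __post_init__(self):
        self.samples = [np.asarray(s, dtype=float) for s in self.samples]
        self.reduced_energies = [np.asarray(u, dtype=float) for u in self.reduced_energies]
        K = len(self.samples)
        for k, (s, u) in enumerate(zip(self.samples, self.reduced_energies)):
            if u.shape != (K, len(s)):
                raise ValueError(
                    f"reduced_energies[{k}] must have shape ({K}, {len(s)})"
                )
            if not np.all(np.isfinite(u)):
                raise ValueError("reduced energies must be finite")

    @property
    def n_states(self) -> int:
        return len(self.samples)


def _sample_frequencies(density: SpectralDistribution, n: int, rng) -> np.ndarray:
    """Inverse-CDF sampling of the unit-area density."""
    w, r = density.omega, np.clip(density.rho, 0.0, None)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (r[1:] + r[:-1]) * np.diff(w))])
    cdf /= cdf[-1]
    u = rng.random(n)
    return np.interp(u, cdf, w)


def _gaussian_process(
    density: SpectralDistribution,
    lam: float,
    temperature: float,
    dt: float,
    n_steps: int,
    n_modes: int,
    rng,
) -> np.ndarray:
    """Mode superposition with exact target covariance in expectation.

    Frequencies are drawn from the density and each mode carries a fixed
    thermal amplitude with two random quadrature phases, so the total
    variance is pinned to 2 lam kB T (no chi-squared spread across
    realisations) and the series is Gaussian to central-limit accuracy for
    n_modes >= 100; the classical autocovariance is
    2 lam kB T <cos(w t)>_rho.
    """
    sigma2 = 2.0 * lam / beta_ev(temperature)
    freqs = _sample_frequencies(density, n_modes, rng)
    phases = rng.uniform(0.0, 2.0 * np.pi, n_modes)
    amps = np.sqrt(2.0 * sigma2 / n_modes) * np.stack(
        [np.cos(phases), np.sin(phases)]
    )
    t = dt * np.arange(n_steps)
    out = np.zeros(n_steps)
    for i0 in range(0, n_modes, 64):  # chunked to bound memory
        ph = np.outer(t, freqs[i0 : i0 + 64]) / HBAR_EV_FS
        out += np.cos(ph) @ amps[0, i0 : i0 + 64] + np.sin(ph) @ amps[1, i0 : i0 + 64]
    return out


def generate_gap_trajectory(
    density: SpectralDistribution,
    temperature: float,
    dt: float,
    n_steps: int,
    n_modes: int = 400,
    seed: int = 0,
    mean: float = 0.0,
    state_label: str = "A",
) -> EnergyGapTrajectory:
    """Stationary Gaussian gap fluctuations with the target spectral density.

    The classical autocovariance is ``2 lam kB T int rho(w) cos(w t/hbar) dw``
    and the lag-0 variance is the linear-response value ``2 lam kB T``.  If
    ``density.parts`` carries an inner/outer decomposition, two independent
    processes are generated from the parts and stored as ``components``
    (molecular = inner, environment = outer).
    """
    if n_modes < 100:
        raise ValueError("n_modes must be >= 100 for a usable Gaussian process")
    if dt <= 0 or n_steps <= 0 or temperature <= 0:
        raise ValueError("dt, n_steps and temperature must be positive")
    rng = np.random.default_rng(seed)
    if density.parts and "inner" in density.parts and "outer" in density.parts:
        inner, outer = density.parts["inner"], density.parts["outer"]
        mol = _gaussian_process(inner, inner.lam, temperature, dt, n_steps, n_modes, rng)
        env = _gaussian_process(outer, outer.lam, temperature, dt, n_steps, n_modes, rng)
        return EnergyGapTrajectory(
            dt=dt,
            values=mol + env + mean,
            state_label=state_label,
            components=(mol + mean, env),
        )
    vals = _gaussian_process(density, density.lam, temperature, dt, n_steps, n_modes, rng)
    return EnergyGapTrajectory(dt=dt, values=vals + mean, state_label=state_label)


def two_state_reduced_energies(
    eps: np.ndarray, delta_A: float, lam: float, temperature: float
) -> np.ndarray:
    """Reduced energies of gap values under the two shifted-harmonic states.

    With the gap itself as the coordinate, ``u_A = (eps - DeltaA - lam)^2 /
    (4 lam kB T)`` and ``u_B = u_A + beta eps`` (the defining identity
    ``V_B - V_A = eps``); the implied free energy difference is
    ``f_B - f_A = beta DeltaA``.
    """
    beta = beta_ev(temperature)
    u_A = beta * (eps - delta_A - lam) ** 2 / (4.0 * lam)
    return np.stack([u_A, u_A + beta * eps])


def generate_two_state_samples(
    delta_A: float,
    lam: float,
    temperature: float,
    n_per_state: int,
    seed: int = 0,
) -> GapSampleSet:
    """Shifted-harmonic gap samples under both electronic states.

    Gaussian with mean ``DeltaA + lam`` under A, ``DeltaA - lam`` under B and
    variance ``2 lam kB T`` under both (equal curvatures).
    """
    if lam <= 0:
        raise ValueError(f"lam must be positive, got {lam}")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(2.0 * lam / beta_ev(temperature))
    xs = [
        rng.normal(delta_A + lam, sigma, n_per_state),
        rng.normal(delta_A - lam, sigma, n_per_state),
    ]
    u = [two_state_reduced_energies(x, delta_A, lam, temperature) for x in xs]
    return GapSampleSet(
        samples=xs, reduced_energies=u, temperature=temperature, labels=["A", "B"]
    )


def generate_umbrella_windows(
    delta_A: float,
    lam: float,
    temperature: float,
    centers,
    curvature: float,
    n_per_window: int,
    seed: int = 0,
) -> GapSampleSet:
    """Harmonically biased windows along the gap coordinate on surface A.

    Window ``i`` samples ``exp(-u_A(eps) - beta*curvature*(eps-c_i)^2/2)``;
    for a harmonic state both factors are Gaussian so the window distribution
    is sampled exactly.  Curvature is in eV per eV^2 of gap displacement.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.size == 0:
        raise ValueError("centers must be non-empty")
    if lam <= 0 or curvature < 0:
        raise ValueError("lam must be positive and curvature non-negative")
    beta = beta_ev(temperature)
    rng = np.random.default_rng(seed)
    var0 = 2.0 * lam / beta
    m_A = delta_A + lam
    prec = 1.0 / var0 + beta * curvature
    xs, us = [], []
    for c in centers:
        mean = (m_A / var0 + beta * curvature * c) / prec
        xs.append(rng.normal(mean, np.sqrt(1.0 / prec), n_per_window))
    for x in xs:
        u_A = beta * (x - m_A) ** 2 / (4.0 * lam)
        us.append(
            np.stack([u_A + 0.5 * beta * curvature * (x - c) ** 2 for c in centers])
        )
    return GapSampleSet(
        samples=xs,
        reduced_energies=us,
        temperature=temperature,
        bias_spec=[(float(c), curvature) for c in centers],
    )


@dataclass(frozen=True)
class ProcessParams:
    """One row of the BD-An process table."""

    initial: str
    final: str
    delta_A: float  # eV
    lam: float  # eV, stored positive
    coupling_cm1: float | None
    rate_s: float | None
    rate_no_recrossing_s: float | None = None
    radiative: bool = False
    lambda_printed_negative: bool = False
    lambda_source: str | None = None


@dataclass(frozen=True)
class BDAnParameterSet:
    """The transcribed BD-An fixture: eight processes, dipoles, global shift."""

    processes: dict[tuple[str, str], ProcessParams]
    dipoles_au: dict[tuple[str, str], float]
    shift_cm1: float
    temperature: float
    delta_A_CS_weller: float
    printed_k_F_SCT_s: float
    version: int = 1

    def __post_init__(self):
        if len(self.processes) != 8:
            raise ValueError("fixture must contain the eight tabulated processes")
        for p in self.processes.values():
            if p.lam <= 0:
                raise ValueError("reorganization energies are stored positive")

    def lookup(self, initial: str, final: str) -> ProcessParams:
        return self.processes[(initial, final)]

    @property
    def delta_A_CS(self) -> float:
        """Simulated charge-separation free energy change (eV)."""
        return self.lookup("SBD", "SCT").delta_A


def bd_an_parameter_set() -> BDAnParameterSet:
    """Load the packaged BD-An parameter fixture.

    Reorganization energies printed with a negative sign in the source table
    (a typographical artifact; ``lam >= 0`` by definition) are stored positive
    with ``lambda_printed_negative=True`` as a provenance flag.
    """
    text = resources.files("bdan.data").joinpath("bdan_parameters.json").read_text()
    raw = json.loads(text)
    procs = {}
    for key, row in raw["processes"].items():
        a, b = key.split("->")
        procs[(a, b)] = ProcessParams(
            initial=a,
            final=b,
            delta_A=row["delta_A_eV"],
            lam=row["lambda_eV"],
            coupling_cm1=row.get("H_cm1"),
            rate_s=row.get("rate_s"),
            rate_no_recrossing_s=row.get("rate_no_recrossing_s"),
            radiative=row.get("radiative", False),
            lambda_printed_negative=row.get("lambda_printed_negative", False),
            lambda_source=row.get("lambda_source"),
        )
    dip = {tuple(k.split(":")): v for k, v in raw["dipoles_au"].items()}
    return BDAnParameterSet(
        processes=procs,
        dipoles_au=dip,
        shift_cm1=raw["shift_cm1"],
        temperature=raw["temperature_K"],
        delta_A_CS_weller=raw["delta_A_CS_weller_eV"],
        printed_k_F_SCT_s=raw["printed_k_F_SCT_s"],
        version=raw["version"],
    )
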