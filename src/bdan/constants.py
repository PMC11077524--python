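"""Physical constants and unit conversions.

Internal units throughout the package: energies and (angular) frequencies in
eV, time in fs, temperature in K.  Phases are always formed as ``omega * t /
HBAR_EV_FS`` so that an "omega" stored in eV is really an energy quantum
``hbar*omega``.  Wavenumbers (cm^-1) are accepted only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

#: reduced Planck constant, eV fs
HBAR_EV_FS = 0.6582119569
#: Boltzmann constant, eV / K
KB_EV_K = 8.617333262e-05
#: wavenumbers per eV
CM1_PER_EV = 8065.544
#: Hartree energy, eV
HARTREE_EV = 27.211386245988
#: fine-structure constant
FINE_STRUCTURE = 7.2973525693e-03
#: atomic unit of time, seconds
ATOMIC_TIME_S = 2.4188843265857e-17
#: femtoseconds per second
FS_PER_S = 1.0e15


def cm1_to_ev(x):
    """Convert wavenumbers (cm^-1) to eV."""
    return x / CM1_PER_EV


def ev_to_cm1(x):
    """Convert eV to wavenumbers (cm^-1)."""
    return x * CM1_PER_EV


def beta_ev(temperature: float) -> float:
    """Inverse temperature 1/(kB T) in eV^-1."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB_EV_K * temperature)


@dataclass(frozen=True)
class UnitConstants:
    """Bundle of the unit constants used by the rate expressions."""

    hbar: float = HBAR_EV_FS
    k_B: float = KB_EV_K
    cm1_per_eV: float = CM1_PER_EV


DEFAULT_TEMPERATURE = 298.15
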