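"""Absorption and composite fluorescence spectra of BD-An.

Builds model spectral distributions for the SBD* and SCT transitions
(inner-sphere Brownian oscillator at ~1400 cm^-1 plus an outer-sphere Debye
component, with the tabulated reorganization energies), computes the
lineshapes with the 805 cm^-1 global excited-state shift, forms the
population/dipole-weighted composite emission for both the simulated and
the Weller charge-separation free energies, and evaluates radiative rates.

Writes results/spectrum_*.csv and results/radiative_rates.csv.
"""

import pathlib

import numpy as np
import pandas as pd

from bdan.bath import AnalyticBathSpec, analytic_distribution, debye_grid
from bdan.constants import cm1_to_ev, ev_to_cm1
from bdan.rates import TwoStateSystem
from bdan.spectra import (
    EmissionWeights,
    composite_fluorescence,
    lineshape_spectrum,
    radiative_rate,
)
from bdan.synthetic import bd_an_parameter_set

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

INNER_CM1 = 1400.0
DEBYE_OMEGA = 0.0047  # eV; acetonitrile-like relaxation (~140 fs)


def make_density(lam_total, inner_fraction):
    bo = AnalyticBathSpec(
        "brownian_oscillator", lam=inner_fraction * lam_total,
        Omega=cm1_to_ev(INNER_CM1), gamma=cm1_to_ev(100.0),
    )
    de = AnalyticBathSpec("debye", lam=(1 - inner_fraction) * lam_total,
                          omega_D=DEBYE_OMEGA)
    return analytic_distribution([de, bo], debye_grid(DEBYE_OMEGA, 1.2, 8000))


def main():
    params = bd_an_parameter_set()
    T = params.temperature
    shift = params.shift_cm1

    # SBD*: weakly displaced, dominantly inner-sphere; SCT: 50/50 split
    d_bd = make_density(params.lookup("SBD", "S0").lam, 0.95)
    d_ct = make_density(params.lookup("SCT", "S0").lam, 0.50)
    sys_bd = TwoStateSystem("SBD", "S0", abs(params.lookup("SBD", "S0").delta_A),
                            d_bd.lam, 0.0, T, density_A=d_bd, density_B=d_bd)
    sys_ct = TwoStateSystem("SCT", "S0", abs(params.lookup("SCT", "S0").delta_A),
                            d_ct.lam, 0.0, T, density_A=d_ct, density_B=d_ct)

    grid = np.linspace(1.2, 3.2, 6000)
    absorption = lineshape_spectrum(sys_bd, "absorption", shift_cm1=shift,
                                    energy_grid=grid)
    em_bd = lineshape_spectrum(sys_bd, "emission", shift_cm1=shift, energy_grid=grid)
    em_ct = lineshape_spectrum(sys_ct, "emission", shift_cm1=shift, energy_grid=grid)

    mu = {"SBD": params.dipoles_au[("SBD", "S0")],
          "SCT": params.dipoles_au[("SCT", "S0")]}
    for tag, dacs in (("computed", params.delta_A_CS),
                      ("weller", params.delta_A_CS_weller)):
        w = EmissionWeights(mu, dacs, T)
        comp = composite_fluorescence({"SBD": em_bd, "SCT": em_ct}, w)
        frac = dict(zip(comp.labels, comp.weights))
        print(f"composite emission ({tag}, dA_CS={dacs:+.3f} eV): "
              f"SBD weight {frac['SBD']:.3f}, SCT weight {frac['SCT']:.3f}")
        pd.DataFrame({
            "energy_eV": comp.omega,
            "wavenumber_cm1": ev_to_cm1(comp.omega),
            "wavelength_nm": 1239.84193 / comp.omega,
            "intensity_per_eV": comp.intensity,
        }).to_csv(OUT / f"spectrum_fluorescence_{tag}.csv", index=False)

    pd.DataFrame({
        "energy_eV": absorption.omega,
        "wavenumber_cm1": ev_to_cm1(absorption.omega),
        "intensity_per_eV": absorption.intensity,
    }).to_csv(OUT / "spectrum_absorption.csv", index=False)

    # radiative rates from the unshifted emission lineshapes (the tabulated
    # reference value is quoted without the empirical spectral shift)
    em_bd0 = lineshape_spectrum(sys_bd, "emission")
    em_ct0 = lineshape_spectrum(sys_ct, "emission")
    k_bd = radiative_rate(em_bd0, mu["SBD"])
    k_ct = radiative_rate(em_ct0, mu["SCT"])
    print(f"k_F(SBD*) = {k_bd.value:.4g} s^-1 (tabulated 1.0747e8)")
    print(f"k_F(SCT)  = {k_ct.value:.4g} s^-1 (mu^2 omega^3-scaled fixture value "
          f"{7.12e6:.3g})")
    pd.DataFrame([
        dict(state="SBD", mu_squared_au=mu["SBD"], k_radiative_s=k_bd.value),
        dict(state="SCT", mu_squared_au=mu["SCT"], k_radiative_s=k_ct.value),
    ]).to_csv(OUT / "radiative_rates.csv", index=False)
    print(f"wrote spectra to {OUT}")


if __name__ == "__main__":
    main()
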