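"""Beyond-golden-rule recrossing for the coarse-grained SCT->S0 model.

Propagates the hierarchical equations of motion for the two-state model
with the printed Debye + underdamped Brownian-oscillator bath
(beta*omega_D = 0.1831, beta*gamma = 4, beta*Omega = 6.76,
beta*lam_D = 10.1459, beta*lam_BO = 8.6780 at 298.15 K, dE = -2.397 eV)
over a grid of diabatic couplings, and reports k_HEOM / k_FGR with the
golden-rule denominator evaluated on the identical bath.  At the full
coupling H = 1904 cm^-1 the ratio quantifies the recrossing correction
applied to the charge-recombination rate.

Writes results/heom_recrossing.csv.  Runtime: a few minutes.
"""

import pathlib

import numpy as np
import pandas as pd

from bdan.bath import AnalyticBathSpec
from bdan.constants import beta_ev, cm1_to_ev, ev_to_cm1
from bdan.heom import HEOMModel, recrossing_factor
from bdan.synthetic import bd_an_parameter_set

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def fig_model(coupling_cm1=1904.0, temperature=298.15):
    beta = beta_ev(temperature)
    debye = AnalyticBathSpec("debye", lam=10.1459 / beta, omega_D=0.1831 / beta)
    bo = AnalyticBathSpec(
        "brownian_oscillator", lam=8.6780 / beta, Omega=6.76 / beta, gamma=4.0 / beta
    )
    return HEOMModel(
        delta_E=-2.397, coupling=cm1_to_ev(coupling_cm1), baths=[debye, bo],
        temperature=temperature, depth=[24, 6, 6], n_matsubara=4,
        matsubara_order=2,
    )


def main():
    params = bd_an_parameter_set()
    H_full = params.lookup("SCT", "S0").coupling_cm1
    model = fig_model(H_full, params.temperature)
    grid_cm1 = np.array([H_full / 20, H_full / 4, H_full / 2, H_full])
    results = recrossing_factor(model, cm1_to_ev(grid_cm1))
    rows = []
    for r in results:
        rows.append(dict(
            H_cm1=ev_to_cm1(r["coupling_eV"]),
            k_heom_s=r["k_heom_s"], k_fgr_s=r["k_fgr_s"], ratio=r["ratio"],
        ))
        print(f"H = {ev_to_cm1(r['coupling_eV']):7.1f} cm^-1: "
              f"k_HEOM = {r['k_heom_s']:.4g}  k_FGR = {r['k_fgr_s']:.4g}  "
              f"ratio = {r['ratio']:.4f}")
    pd.DataFrame(rows).to_csv(OUT / "heom_recrossing.csv", index=False)
    full = rows[-1]["ratio"]
    print(f"\nrecrossing factor at the physical coupling: {full:.3f} "
          "(applied to the golden-rule SCT->S0 rate)")
    print(f"wrote {OUT / 'heom_recrossing.csv'}")


if __name__ == "__main__":
    main()
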