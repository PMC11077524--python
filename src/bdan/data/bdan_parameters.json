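{
  "version": 1,
  "description": "Two-state process descriptors for the BODIPY-anthracene (BD-An) dyad in acetonitrile: free energy changes, reorganization energies, diabatic/spin-orbit couplings and reference rate constants for the eight electronic processes of the six-state photophysics network.",
  "units": {
    "delta_A": "eV",
    "lambda": "eV",
    "H": "cm^-1",
    "rate": "s^-1",
    "mu_squared": "atomic units",
    "shift": "cm^-1",
    "temperature": "K"
  },
  "temperature_K": 298.15,
  "shift_cm1": 805.0,
  "delta_A_CS_weller_eV": 0.13,
  "dipoles_au": {
    "SBD:S0": 7.59,
    "SCT:S0": 0.54
  },
  "printed_k_F_SCT_s": 7.7e8,
  "printed_k_F_SCT_note": "printed with an inconsistent exponent; the mu^2 omega^3 scaled value ~7e6 s^-1 is what the branching fractions imply",
  "processes": {
    "SBD->SCT": {"delta_A_eV": -0.057, "lambda_eV": 0.550, "H_cm1": 99.0, "rate_s": 1.46e11},
    "SBD->S0":  {"delta_A_eV": -2.4542, "lambda_eV": 0.0877, "H_cm1": null, "rate_s": 1.0747e8, "radiative": true, "lambda_source": "linear_response"},
    "SCT->S0":  {"delta_A_eV": -2.397, "lambda_eV": 0.483, "H_cm1": 1904.0, "rate_s": 3.4e7, "rate_no_recrossing_s": 3.6e7},
    "SCT->TBD": {"delta_A_eV": -0.826, "lambda_eV": 0.584, "H_cm1": 0.79, "rate_s": 7.9e7},
    "SCT->TAN": {"delta_A_eV": -0.524, "lambda_eV": 0.477, "H_cm1": 0.63, "rate_s": 9.7e7, "lambda_printed_negative": true},
    "SCT->TCT": {"delta_A_eV": -0.112, "lambda_eV": 0.119, "H_cm1": 0.21, "rate_s": 2.86e7, "lambda_printed_negative": true},
    "TAN->TBD": {"delta_A_eV": -0.302, "lambda_eV": 0.565, "H_cm1": 2.57, "rate_s": 1.09e9},
    "TBD->S0":  {"delta_A_eV": -1.638, "lambda_eV": 0.512, "H_cm1": 0.19, "rate_s": 1.045e4, "lambda_source": "umbrella_sampling_nonpolarizable"}
  }
}
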