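{
  "comment": "Reduced per-element non-bonded parameters for the 6-12 + distance-dependent-dielectric scoring model. rstar is Rmin/2 in Angstrom (pairwise Rmin_ij = rstar_i + rstar_j), eps in kcal/mol (pairwise eps_ij = sqrt(eps_i * eps_j)). Values are consolidated per-element from a published united-atom force-field table; user-supplied files override.",
  "coulomb_constant": 332.064,
  "dielectric": "2r",
  "elements": {
    "H": {"rstar": 0.60, "eps": 0.0157},
    "C": {"rstar": 1.908, "eps": 0.086},
    "N": {"rstar": 1.824, "eps": 0.170},
    "O": {"rstar": 1.661, "eps": 0.210},
    "S": {"rstar": 2.000, "eps": 0.250},
    "P": {"rstar": 2.100, "eps": 0.200},
    "F": {"rstar": 1.750, "eps": 0.061},
    "CL": {"rstar": 1.948, "eps": 0.265},
    "BR": {"rstar": 2.220, "eps": 0.320},
    "K": {"rstar": 2.658, "eps": 0.000328},
    "NA": {"rstar": 1.868, "eps": 0.00277},
    "CA": {"rstar": 1.713, "eps": 0.4598},
    "MG": {"rstar": 0.793, "eps": 0.8947},
    "ZN": {"rstar": 1.100, "eps": 0.0125},
    "CD": {"rstar": 1.300, "eps": 0.0130},
    "CS": {"rstar": 3.395, "eps": 0.0000806},
    "RB": {"rstar": 2.956, "eps": 0.00017},
    "BA": {"rstar": 2.019, "eps": 0.1869},
    "TL": {"rstar": 1.800, "eps": 0.0500}
  }
}
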