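{
  "comment": "Default partial-charge table. Residue entries give per-atom charges in elementary units and must sum to the declared formal charge. element_fallback assigns charges by element to atoms of residues without an entry (protein backbone/sidechain atoms default to neutral in the reduced model; monatomic ions carry their formal charge).",
  "residues": {
    "LIG": {"formal_charge": 1.0, "atoms": {"N1": 1.0}},
    "K": {"formal_charge": 1.0, "atoms": {"K": 1.0}},
    "NA": {"formal_charge": 1.0, "atoms": {"NA": 1.0}},
    "CS": {"formal_charge": 1.0, "atoms": {"CS": 1.0}},
    "RB": {"formal_charge": 1.0, "atoms": {"RB": 1.0}},
    "TL": {"formal_charge": 1.0, "atoms": {"TL": 1.0}},
    "CA": {"formal_charge": 2.0, "atoms": {"CA": 2.0}},
    "MG": {"formal_charge": 2.0, "atoms": {"MG": 2.0}},
    "ZN": {"formal_charge": 2.0, "atoms": {"ZN": 2.0}},
    "CD": {"formal_charge": 2.0, "atoms": {"CD": 2.0}},
    "BA": {"formal_charge": 2.0, "atoms": {"BA": 2.0}},
    "CL": {"formal_charge": -1.0, "atoms": {"CL": -1.0}},
    "BR": {"formal_charge": -1.0, "atoms": {"BR": -1.0}}
  },
  "backbone_dipole": {
    "comment": "Optional reduced backbone polarity applied to protein residues when enabled: amide and carbonyl partial charges; each residue stays net-neutral.",
    "N": -0.38,
    "CA": 0.38,
    "C": 0.38,
    "O": -0.38,
    "CB": 0.0
  },
  "element_fallback": {"default": 0.0}
}
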