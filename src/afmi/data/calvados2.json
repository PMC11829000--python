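{
  "name": "CALVADOS-2 one-bead-per-residue parameters",
  "version": "2",
  "reference": "Tesei & Lindorff-Larsen, Open Research Europe 2:94 (2022); Tesei et al., PNAS 118:e2111696118 (2021)",
  "epsilon_kj_mol": 0.8368,
  "bond_k_kj_mol_nm2": 8033.0,
  "bond_r0_nm": 0.38,
  "cutoff_ah_nm": 2.4,
  "cutoff_dh_nm": 4.0,
  "histidine_pka": 6.0,
  "residues": {
    "A": {"sigma_nm": 0.504, "lambda": 0.2743297969040348, "charge": 0.0, "mass_amu": 71.0779},
    "R": {"sigma_nm": 0.656, "lambda": 0.7307624767517166, "charge": 1.0, "mass_amu": 156.1857},
    "N": {"sigma_nm": 0.568, "lambda": 0.4255859009787431, "charge": 0.0, "mass_amu": 114.1026},
    "D": {"sigma_nm": 0.558, "lambda": 0.0416040480605567, "charge": -1.0, "mass_amu": 115.0874},
    "C": {"sigma_nm": 0.548, "lambda": 0.5615435099141777, "charge": 0.0, "mass_amu": 103.1429},
    "Q": {"sigma_nm": 0.602, "lambda": 0.3934318551056041, "charge": 0.0, "mass_amu": 128.1292},
    "E": {"sigma_nm": 0.592, "lambda": 0.0006935460962935, "charge": -1.0, "mass_amu": 129.114},
    "G": {"sigma_nm": 0.45, "lambda": 0.7012713677972457, "charge": 0.0, "mass_amu": 57.0513},
    "H": {"sigma_nm": 0.608, "lambda": 0.4663667290557992, "charge": 0.0, "mass_amu": 137.1393},
    "I": {"sigma_nm": 0.618, "lambda": 0.5423623610671892, "charge": 0.0, "mass_amu": 113.1576},
    "L": {"sigma_nm": 0.618, "lambda": 0.6440005007782226, "charge": 0.0, "mass_amu": 113.1576},
    "K": {"sigma_nm": 0.636, "lambda": 0.1790211738990582, "charge": 1.0, "mass_amu": 128.1723},
    "M": {"sigma_nm": 0.618, "lambda": 0.5308481134337497, "charge": 0.0, "mass_amu": 131.1961},
    "F": {"sigma_nm": 0.636, "lambda": 0.8672358982062975, "charge": 0.0, "mass_amu": 147.1739},
    "P": {"sigma_nm": 0.556, "lambda": 0.3593126576364644, "charge": 0.0, "mass_amu": 97.1152},
    "S": {"sigma_nm": 0.518, "lambda": 0.4625416811611541, "charge": 0.0, "mass_amu": 87.0773},
    "T": {"sigma_nm": 0.562, "lambda": 0.3713162976273964, "charge": 0.0, "mass_amu": 101.1039},
    "W": {"sigma_nm": 0.678, "lambda": 0.9893764740371644, "charge": 0.0, "mass_amu": 186.2099},
    "Y": {"sigma_nm": 0.646, "lambda": 0.9774611449343455, "charge": 0.0, "mass_amu": 163.1733},
    "V": {"sigma_nm": 0.586, "lambda": 0.2083769608174481, "charge": 0.0, "mass_amu": 99.1311}
  }
}
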