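"""Physical constants in the GROMACS-style unit system (nm, ps, amu, kJ/mol)."""

#: Boltzmann constant, kJ mol^-1 K^-1.
KB = 0.008314462618

#: Coulomb prefactor e^2 N_A / (4 pi eps_0), kJ mol^-1 nm e^-2.
COULOMB = 138.935458

#: Avogadro number, mol^-1.
AVOGADRO = 6.02214076e23

#: Angstrom per nanometer.
ANGSTROM_PER_NM = 10.0
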