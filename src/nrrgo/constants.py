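"""Physical constants and unit conventions.

Internal unit system: kcal/mol (energy), Angstrom (length), ps (time),
amu (mass), Kelvin (temperature).  Velocities are A/ps.  The only
non-trivial conversion is energy -> amu*A^2/ps^2 for the integrator,
which is exactly 418.4 because N_A * amu * (A/ps)^2 = 10 J/mol.
"""

#: Boltzmann constant, kcal/mol/K
KB = 0.0019872041

#: 1 kcal/mol expressed in amu * A^2 / ps^2
KCAL_TO_MD = 418.4

#: 1 kcal/(mol*A) expressed in pN, used wherever forces are reported
PN_PER_KCAL_MOL_A = 69.4786

#: average amino-acid residue masses (amu), water subtracted
RESIDUE_MASS = {
    "G": 57.05, "A": 71.08, "S": 87.08, "P": 97.12, "V": 99.13,
    "T": 101.10, "C": 103.14, "L": 113.16, "I": 113.16, "N": 114.10,
    "D": 115.09, "Q": 128.13, "K": 128.17, "E": 129.12, "M": 131.19,
    "H": 137.14, "F": 147.18, "R": 156.19, "Y": 163.18, "W": 186.21,
}

#: calcium ion mass (amu)
CALCIUM_MASS = 40.08

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: backbone heavy-atom names of a C-alpha-traced residue
BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")
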