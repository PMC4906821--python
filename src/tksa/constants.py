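"""Physical constants and lookup tables shared across the package.

Everything tunable-by-table lives here so a run log can cite a single
module for provenance: van der Waals radii, model-compound pKa values,
reference maximal accessibilities, and the electrostatic conversion
constant.
"""

from __future__ import annotations

# e^2 * N_A / (4 pi eps_0), for charges in units of e and distances in
# Angstrom, yielding energies in kJ/mol.
COULOMB_K_KJ_A_MOL = 1389.35

# Debye screening: kappa (1/Angstrom) = KAPPA_COEF * sqrt(I in mol/L),
# valid for water near 298 K.
KAPPA_COEF_PER_A = 0.3287

# Bondi-style van der Waals radii (Angstrom), used for solvent-accessible
# surface area. Unlisted elements fall back to VDW_DEFAULT.
VDW_RADII_A = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
}
VDW_DEFAULT_A = 1.70

# Model-compound pKa values for ionizable groups. Keys are 3-letter
# residue codes plus the terminal-group tags.
PKA_TABLE = {
    "ASP": 4.0,
    "GLU": 4.4,
    "HIS": 6.3,
    "LYS": 10.4,
    "ARG": 12.0,
    "CYS": 8.3,
    "TYR": 10.1,
    "NTERM": 8.0,
    "CTERM": 3.6,
}

# Groups that carry negative charge when deprotonated.
ACIDIC_GROUPS = {"ASP", "GLU", "CYS", "TYR", "CTERM"}
# Groups that carry positive charge when protonated.
BASIC_GROUPS = {"HIS", "LYS", "ARG", "NTERM"}

# Theoretical maximal accessible surface areas (Angstrom^2) of residue X
# in an extended Gly-X-Gly tripeptide (Tien et al. 2013, theoretical set).
# Used to normalize per-residue SASA to a [0, 1] fraction.
MAX_ASA_TRIPEPTIDE_A2 = {
    "ALA": 129.0,
    "ARG": 274.0,
    "ASN": 195.0,
    "ASP": 193.0,
    "CYS": 167.0,
    "GLN": 225.0,
    "GLU": 223.0,
    "GLY": 104.0,
    "HIS": 224.0,
    "ILE": 197.0,
    "LEU": 201.0,
    "LYS": 236.0,
    "MET": 224.0,
    "PHE": 240.0,
    "PRO": 159.0,
    "SER": 155.0,
    "THR": 172.0,
    "TRP": 285.0,
    "TYR": 263.0,
    "VAL": 174.0,
}

# Canonical 3-letter -> 1-letter residue code mapping.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
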