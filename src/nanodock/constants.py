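"""Physical constants and unit conversions.

All energies in the package are kJ/mol, all distances nm, temperatures K,
charges in units of the elementary charge e, surface potentials in mV.
"""

from scipy import constants as _sc

#: Boltzmann constant expressed as the molar gas constant, kJ mol^-1 K^-1.
KB_KJMOL: float = _sc.R / 1000.0

#: Energy of one elementary charge at 1 mV, per mole: F / 1e6, kJ mol^-1 mV^-1.
#: Converts q[e] * potential[mV] into kJ/mol.
F_MV: float = _sc.physical_constants["Faraday constant"][0] / 1.0e6

#: Elementary charge, C.
E_CHARGE: float = _sc.e

#: Vacuum permittivity, F/m.
EPS0: float = _sc.epsilon_0

#: Boltzmann constant, J/K.
KB_J: float = _sc.k

#: Avogadro constant, mol^-1.
N_AVOGADRO: float = _sc.N_A

#: Conversion: mol/L of a 1:1 salt -> number density in nm^-3 (per species).
MOLAR_TO_NM3: float = _sc.N_A / 1.0e24

#: Angstrom -> nm.
ANGSTROM_TO_NM: float = 0.1

#: The 20 standard amino-acid three-letter codes.
STANDARD_AA3 = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)

#: Common nonstandard residues mapped to their standard parent.
NONSTANDARD_AA_MAP = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine (closest standard analogue)
    "PYL": "LYS",  # pyrrolysine
    "HYP": "PRO",  # hydroxyproline
    "SEP": "SER",  # phosphoserine
    "TPO": "THR",  # phosphothreonine
    "PTR": "TYR",  # phosphotyrosine
    "CSO": "CYS",
    "MLY": "LYS",
    "KCX": "LYS",
}
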