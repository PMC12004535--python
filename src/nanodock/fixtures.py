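"""Deterministic toy-protein generators.

These emit small, valid PDB texts so every pipeline stage can be exercised
without downloading a structure: an ideal alpha-helix CA trace, and a
"dipolar rod" with a cationic (LYS) end and an anionic (ASP) end that must
orient its cationic end toward a negatively charged particle when only
electrostatics act.
"""

from __future__ import annotations

import numpy as np

__all__ = ["make_helix", "make_dipolar_rod", "pdb_from_ca"]

#: Ideal alpha-helix CA-trace geometry: rise per residue (nm), helix radius
#: (nm) and twist per residue (deg).
HELIX_RISE = 0.15
HELIX_RADIUS = 0.23
HELIX_TWIST = 100.0

_AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def pdb_from_ca(residues: list[str], positions_nm: np.ndarray, chain: str = "A") -> str:
    """Render CA-only ATOM records (input positions in nm, output PDB in A)."""
    lines = []
    for i, (res, p) in enumerate(zip(residues, np.asarray(positions_nm, dtype=float))):
        x, y, z = p * 10.0
        lines.append(
            f"ATOM  {i + 1:5d}  CA  {res:>3s} {chain}{i + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_helix(n: int, sequence: str | None = None, seed: int = 0) -> str:
    """PDB text of an n-residue ideal alpha-helix CA trace along z.

    ``sequence`` is a one-letter string (repeated cyclically if shorter
    than n); when omitted, a seeded random sequence is drawn so the same
    (n, seed) always yields byte-identical output.
    """
    if n < 1:
        raise ValueError("need at least one residue")
    if sequence is None:
        rng = np.random.default_rng(seed)
        letters = sorted(_AA1TO3)
        sequence = "".join(rng.choice(letters) for _ in range(n))
    residues = [_AA1TO3[sequence[i % len(sequence)].upper()] for i in range(n)]
    i = np.arange(n)
    ang = np.deg2rad(HELIX_TWIST * i)
    pos = np.column_stack(
        [HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang), HELIX_RISE * i]
    )
    return pdb_from_ca(residues, pos)


def make_dipolar_rod(n_pos: int = 4, n_neg: int = 4, length: float = 3.0,
                     n_spacer: int = 4) -> str:
    """PDB text of a straight rod: LYS cluster at one end, ASP at the other.

    Beads are spaced evenly along the rod axis; GLY spacers sit between the
    charged ends.  With zeroed surface PMFs and a charged particle, the
    heatmap minimum of this rod must fall in the hemisphere presenting the
    end whose charge is attracted to the surface.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one bead per charged end")
    residues = ["LYS"] * n_pos + ["GLY"] * n_spacer + ["ASP"] * n_neg
    n = len(residues)
    z = np.linspace(0.0, length, n)
    pos = np.column_stack([np.zeros(n), np.zeros(n), z])
    return pdb_from_ca(residues, pos)
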