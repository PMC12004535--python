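"""Prepare a protein for docking: read, coarse-grain, protonate, canonicalize.

Builds a 10-residue helix, reduces it to one bead per residue at the CA
positions, assigns Henderson-Hasselbalch fractional charges at pH 7.3, and
moves it into the canonical principal-axis frame (longest axis on z).
"""

import tempfile

import numpy as np

from nanodock import assign_charges, canonicalize, coarse_grain, read_pdb
from nanodock.fixtures import make_helix

with tempfile.NamedTemporaryFile("w", suffix=".pdb") as fh:
    fh.write(make_helix(10, sequence="ACDEFGHIKL"))
    fh.flush()
    protein = coarse_grain(read_pdb(fh.name))

protein = assign_charges(protein, ph=7.3)
protein = canonicalize(protein)

print(f"residues: {protein.n_aa}")
print(f"net charge at pH 7.3: {protein.charges().sum():+.3f} e")
ext = protein.positions().max(axis=0) - protein.positions().min(axis=0)
print(f"extents along x, y, z (nm): {np.round(ext, 3)}")
# The z extent is the largest: the canonical frame puts the long axis on z,
# so the orientation angles (phi, theta) have a fixed, reproducible meaning.
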