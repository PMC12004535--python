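"""Electrostatic steering: a charge-dipole rod orients on a charged particle.

With all surface PMFs and Hamaker constants zeroed, only screened
electrostatics act.  A rod with a LYS (+) end and an ASP (-) end docked on
a -50 mV particle must point its cationic end at the surface; theta < 90
or > 90 tells which hemisphere of protein orientations won.
"""

import tempfile

import numpy as np

from nanodock import (
    Environment,
    NanoparticleSpec,
    ScanConfig,
    assign_charges,
    canonicalize,
    coarse_grain,
    debye_kappa,
    dock,
    read_pdb,
    synth_material,
)
from nanodock.constants import STANDARD_AA3
from nanodock.fixtures import make_dipolar_rod

with tempfile.NamedTemporaryFile("w", suffix=".pdb") as fh:
    fh.write(make_dipolar_rod(n_pos=4, n_neg=4, length=3.0))
    fh.flush()
    rod = canonicalize(assign_charges(coarse_grain(read_pdb(fh.name)), ph=7.0))

zeros = {aa: 0.0 for aa in STANDARD_AA3}
mat = synth_material(depth_map=zeros, hamaker=zeros)  # electrostatics only
env = Environment()
cfg = ScanConfig(delta=15.0, n_bin=2, seed=2)

for zeta in (-50.0, 0.0):
    np_spec = NanoparticleSpec(R_NP=15.0, zeta=zeta, material_id="TESTMAT")
    emap, res = dock(rod, np_spec, mat, debye_kappa(env), cfg, env.T)
    spread = emap.E.max() - emap.E.min()
    print(f"zeta = {zeta:+.0f} mV: E_min = {res.e_min:8.3f} kJ/mol at "
          f"theta = {res.min_orientation.theta:5.1f} deg; map spread = {spread:.3f} kJ/mol")

z_lys = np.mean([b.position[2] for b in rod.beads if b.residue_name == "LYS"])
side = "theta < 90" if z_lys > 0 else "theta > 90"
print(f"LYS end sits at z = {z_lys:+.2f} nm in the protein frame, so the "
      f"cationic-end-down orientations are at {side}.")
# At zeta = 0 the map is flat (nothing to prefer); at -50 mV the minimum
# falls in the LYS hemisphere -- pure electrostatic orientation steering.
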