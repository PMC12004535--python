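import numpy as np
import pytest

from nanodock import (
    Environment,
    NanoparticleSpec,
    ScanConfig,
    assign_charges,
    canonicalize,
    coarse_grain,
    debye_kappa,
    read_pdb,
    synth_material,
)
from nanodock.fixtures import make_helix
from nanodock.structures import Bead, CGProtein


@pytest.fixture(scope="session")
def material():
    """Synthetic test material (9-3 wall PMFs, nonzero Hamaker constants)."""
    return synth_material()


@pytest.fixture(scope="session")
def env():
    return Environment()  # T=309.75 K, I=0.15 M, pH 7


@pytest.fixture(scope="session")
def screening(env):
    return debye_kappa(env)


@pytest.fixture(scope="session")
def np_spec():
    return NanoparticleSpec(R_NP=15.0, zeta=-20.0, material_id="TESTMAT", hkl="000")


@pytest.fixture()
def helix_pdb(tmp_path):
    path = tmp_path / "helix.pdb"
    path.write_text(make_helix(10, sequence="ACDEFGHIKL"))
    return path


@pytest.fixture()
def helix_protein(helix_pdb):
    protein = coarse_grain(read_pdb(helix_pdb))
    protein = assign_charges(protein, 7.0)
    return canonicalize(protein)


@pytest.fixture()
def coarse_cfg():
    """Low-resolution scan configuration that keeps tests fast."""
    return ScanConfig(delta=45.0, n_bin=2, seed=7)


def make_protein(positions, residues=None, charges=None, chain="A"):
    """Build a CGProtein directly from arrays (test helper)."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    residues = residues or ["GLY"] * n
    charges = charges if charges is not None else [0.0] * n
    beads = [
        Bead(index=i, residue_name=residues[i], chain_id=chain, residue_seq=i + 1,
             position=positions[i], charge=float(charges[i]))
        for i in range(n)
    ]
    return CGProtein(beads=beads)


@pytest.fixture(scope="session")
def zero_material():
    """Material with all-zero PMFs and Hamaker constants (isolates electrostatics)."""
    from nanodock.constants import STANDARD_AA3

    zero = {aa: 0.0 for aa in STANDARD_AA3}
    return synth_material(depth_map=zero, hamaker=zero)
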