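"""Per-residue material parameters: Hamaker constants and tabulated PMFs.

A material is described by two parameter sets per amino-acid type: a
Hamaker constant A_i (kJ/mol) governing the long-range van der Waals
attraction to the nanoparticle core, and a short-range surface potential
of mean force sampled on a surface-separation grid (nm, kJ/mol).  The PMFs
are consumed as data; in production they come from enhanced-sampling
atomistic simulations of single residues at the material surface.

On disk a material lives under ``<root>/<material>/<hkl>/`` with one
two-column PMF file ``<AA3>.dat`` per residue plus ``material.dat``
holding the Hamaker constants; ``hkl`` is the Miller-plane label ("000"
for amorphous materials).

:func:`synth_material` builds a fully synthetic material from a 9-3 wall
potential so that the entire pipeline can run and be tested without any
external parameter set.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .constants import STANDARD_AA3

__all__ = [
    "PMFTable",
    "MaterialDB",
    "load_material",
    "save_material",
    "synth_material",
    "pmf_value",
    "PMF_WALL_CAP",
]

#: Cap on the extrapolated repulsive wall, kJ/mol.  Far above any thermally
#: accessible energy; keeps Boltzmann weights finite as h -> 0.
PMF_WALL_CAP = 500.0

DEFAULT_R_CUTOFF = 1.0  # nm


@dataclass(frozen=True)
class PMFTable:
    """Tabulated surface PMF for one residue type: u(h), h in nm, u in kJ/mol."""

    h: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        u = np.asarray(self.u, dtype=float)
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "u", u)
        if h.size < 2:
            raise ValueError("PMF table needs at least 2 nodes")
        if h[0] < 0:
            raise ValueError("PMF grid starts below h = 0")
        if not np.all(np.diff(h) > 0):
            raise ValueError("PMF grid must be strictly increasing")
        if abs(u[-1]) > 0.5:
            raise ValueError(
                f"PMF not decayed at last node: u({h[-1]:.3f}) = {u[-1]:.3f} kJ/mol"
            )


@dataclass(frozen=True)
class MaterialDB:
    material_id: str
    hkl: str
    hamaker: dict[str, float]  # residue -> A_i, kJ/mol
    pmf: dict[str, PMFTable]
    r_cutoff: float = DEFAULT_R_CUTOFF  # nm

    def __post_init__(self) -> None:
        missing = STANDARD_AA3 - set(self.hamaker)
        if missing:
            raise ValueError(f"Hamaker constants missing for: {sorted(missing)}")
        missing = STANDARD_AA3 - set(self.pmf)
        if missing:
            raise ValueError(f"PMF tables missing for: {sorted(missing)}")
        if not 0.0 < self.r_cutoff <= 2.0:
            raise ValueError(f"r_cutoff out of (0, 2.0] nm: {self.r_cutoff}")


def _material_dir(root, material_id: str, hkl: str) -> str:
    return os.path.join(str(root), material_id, hkl)


def load_material(root, material_id: str, hkl: str, r_cutoff: float = DEFAULT_R_CUTOFF) -> MaterialDB:
    """Load a material parameter set from ``<root>/<material>/<hkl>/``."""
    d = _material_dir(root, material_id, hkl)
    ham_path = os.path.join(d, "material.dat")
    if not os.path.isfile(ham_path):
        raise FileNotFoundError(f"Hamaker file not found: {ham_path}")
    hamaker: dict[str, float] = {}
    with open(ham_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            aa, a = line.split()
            hamaker[aa] = float(a)
    pmf: dict[str, PMFTable] = {}
    for aa in sorted(STANDARD_AA3):
        path = os.path.join(d, f"{aa}.dat")
        if not os.path.isfile(path):
            raise FileNotFoundError(f"missing PMF file for {aa}: {path}")
        data = np.loadtxt(path, comments="#", ndmin=2)
        pmf[aa] = PMFTable(h=data[:, 0], u=data[:, 1])
    return MaterialDB(material_id=material_id, hkl=hkl, hamaker=hamaker, pmf=pmf, r_cutoff=r_cutoff)


def save_material(mat: MaterialDB, root) -> str:
    """Write a MaterialDB to the on-disk layout; returns the material directory."""
    d = _material_dir(root, mat.material_id, mat.hkl)
    os.makedirs(d, exist_ok=True)
    with open(os.path.join(d, "material.dat"), "w") as fh:
        fh.write(f"# Hamaker constants (kJ/mol) for {mat.material_id} hkl={mat.hkl}\n")
        for aa in sorted(mat.hamaker):
            fh.write(f"{aa} {mat.hamaker[aa]:.17g}\n")
    for aa, table in mat.pmf.items():
        with open(os.path.join(d, f"{aa}.dat"), "w") as fh:
            fh.write(f"# PMF for {aa} on {mat.material_id} hkl={mat.hkl}; h_nm  u_kJ/mol\n")
            for h, u in zip(table.h, table.u):
                fh.write(f"{h:.17g} {u:.17g}\n")
    return d


#: Relative well depths of the default synthetic material (kJ/mol).
#: Loosely patterned on the generic trend that aromatic and sulfur-bearing
#: side chains bind inorganic surfaces most strongly; purely synthetic.
DEFAULT_SYNTH_DEPTHS = {
    "ALA": 6.0, "ARG": 14.0, "ASN": 9.0, "ASP": 10.0, "CYS": 16.0,
    "GLN": 10.0, "GLU": 11.0, "GLY": 5.0, "HIS": 15.0, "ILE": 8.0,
    "LEU": 8.0, "LYS": 12.0, "MET": 15.0, "PHE": 18.0, "PRO": 7.0,
    "SER": 7.0, "THR": 7.5, "TRP": 20.0, "TYR": 19.0, "VAL": 7.5,
}

#: Default synthetic Hamaker constants (kJ/mol), scaled with the depths.
DEFAULT_SYNTH_HAMAKER = {aa: 0.5 * d for aa, d in DEFAULT_SYNTH_DEPTHS.items()}


def synth_material(
    depth_map: dict[str, float] | None = None,
    sigma: float = 0.35,
    cutoff: float = DEFAULT_R_CUTOFF,
    grid_step: float = 0.025,
    hamaker: dict[str, float] | None = None,
    material_id: str = "TESTMAT",
    hkl: str = "000",
) -> MaterialDB:
    """Build a synthetic MaterialDB from a 9-3 wall potential.

    Each residue's PMF is u(h) = eps * [(2/15)(sigma/(h+sigma))^9
    - (sigma/(h+sigma))^3], shifted so u(cutoff) = 0 exactly, tabulated
    from h = 0 to the cutoff with the given step.  ``depth_map`` sets the
    per-residue energy scale eps (kJ/mol); sigma (nm) sets the range.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    depths = dict(DEFAULT_SYNTH_DEPTHS if depth_map is None else depth_map)
    for aa in STANDARD_AA3:
        depths.setdefault(aa, 0.0)
    ham = dict(DEFAULT_SYNTH_HAMAKER if hamaker is None else hamaker)
    for aa in STANDARD_AA3:
        ham.setdefault(aa, 0.0)
    n = int(round(cutoff / grid_step))
    h = np.linspace(0.0, cutoff, n + 1)

    def wall(hh: np.ndarray, eps: float) -> np.ndarray:
        s = sigma / (hh + sigma)
        return eps * ((2.0 / 15.0) * s**9 - s**3)

    pmf = {}
    for aa in STANDARD_AA3:
        u = wall(h, depths[aa])
        u = u - u[-1]  # exact zero at the cutoff node
        pmf[aa] = PMFTable(h=h, u=u)
    return MaterialDB(material_id=material_id, hkl=hkl, hamaker=ham, pmf=pmf, r_cutoff=cutoff)


def pmf_value(table: PMFTable, h) -> np.ndarray | float:
    """Interpolate the tabulated PMF at separation(s) h (nm).

    Linear interpolation on the grid; zero beyond the last node; below the
    first node, linear extrapolation from the first two nodes capped at
    +500 kJ/mol (hard repulsive wall).
    """
    scalar = np.isscalar(h) or np.ndim(h) == 0
    h_arr = np.atleast_1d(np.asarray(h, dtype=float))
    if np.any(h_arr < 0):
        raise ValueError("separation h must be >= 0")
    u = np.interp(h_arr, table.h, table.u, right=0.0)
    below = h_arr < table.h[0]
    if np.any(below):
        slope = (table.u[1] - table.u[0]) / (table.h[1] - table.h[0])
        extrap = table.u[0] + slope * (h_arr[below] - table.h[0])
        u[below] = np.minimum(extrap, PMF_WALL_CAP)
    return float(u[0]) if scalar else u
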