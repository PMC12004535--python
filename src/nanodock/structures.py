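"""Protein input and the coarse-grained rigid-body representation.

A protein is reduced to one bead per residue, centred on the residue's
alpha-carbon.  Before docking the bead cloud is moved to its geometric
centroid and rotated into a canonical principal-axis frame: the axis of
largest spatial extent along z, the second-largest along y.  Orientations
on the nanoparticle are then parameterised by two angles (phi, theta): the
unit vector with polar angle theta and azimuth phi in the canonical protein
frame is the direction that ends up pointing at the nanoparticle surface,
realised by the rotation R_y(180deg - theta) @ R_z(-phi).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ANGSTROM_TO_NM, NONSTANDARD_AA_MAP, STANDARD_AA3

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Bead",
    "CGProtein",
    "Orientation",
    "EmptyStructureError",
    "read_pdb",
    "coarse_grain",
    "canonicalize",
    "orientation_matrix",
    "orient",
]


class EmptyStructureError(ValueError):
    """Raised when no usable residues remain after filtering."""


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM record, coordinates already converted to nm."""

    serial: int
    atom_name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    icode: str
    position: np.ndarray  # (3,), nm


@dataclass
class Bead:
    """One coarse-grained residue bead (position nm, charge in e)."""

    index: int
    residue_name: str
    chain_id: str
    residue_seq: int
    position: np.ndarray  # (3,), nm
    charge: float = 0.0
    icode: str = ""


@dataclass
class CGProtein:
    beads: list[Bead] = field(default_factory=list)

    @property
    def n_aa(self) -> int:
        return len(self.beads)

    def positions(self) -> np.ndarray:
        """(n_aa, 3) array of bead positions in nm."""
        return np.array([b.position for b in self.beads], dtype=float).reshape(-1, 3)

    def charges(self) -> np.ndarray:
        return np.array([b.charge for b in self.beads], dtype=float)

    def residue_names(self) -> list[str]:
        return [b.residue_name for b in self.beads]

    def with_positions(self, pos: np.ndarray) -> "CGProtein":
        beads = [replace(b, position=np.asarray(p, dtype=float)) for b, p in zip(self.beads, pos)]
        return CGProtein(beads=beads)


@dataclass(frozen=True)
class Orientation:
    """Heatmap coordinates: phi in [0, 360) deg, theta in [0, 180] deg."""

    phi: float
    theta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi < 360.0) or not (0.0 <= self.theta <= 180.0):
            raise ValueError(f"orientation out of range: phi={self.phi}, theta={self.theta}")


def read_pdb(path) -> list[AtomRecord]:
    """Parse ATOM records from a PDB file into nm-unit atom records.

    Keeps standard amino acids only (common modified residues such as MSE
    are renamed to their parent); HETATM lines, waters and ligands are
    dropped.  For alternate locations the first-listed conformer of each
    atom is kept.  Only the first MODEL of a multi-model file is read.

    Raises
    ------
    EmptyStructureError
        If no standard-residue ATOM record survives filtering.
    """
    records: list[AtomRecord] = []
    seen: set[tuple] = set()  # (chain, resSeq, iCode, atom_name) -> first altLoc wins
    serial = 0
    in_first_model = True
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "ENDMDL":
                in_first_model = False
            if not in_first_model:
                continue
            if rec != "ATOM  ":
                continue
            resname = line[17:20].strip()
            if resname not in STANDARD_AA3:
                mapped = NONSTANDARD_AA_MAP.get(resname)
                if mapped is None:
                    logger.warning("dropping nonstandard residue %s", resname)
                    continue
                resname = mapped
            atom_name = line[12:16].strip()
            chain = line[21]
            resseq = int(line[22:26])
            icode = line[26].strip()
            key = (chain, resseq, icode, atom_name)
            if key in seen:  # later altLoc of an atom already kept
                continue
            seen.add(key)
            xyz = np.array(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])], dtype=float
            ) * ANGSTROM_TO_NM
            if not np.all(np.isfinite(xyz)):
                raise ValueError(f"non-finite coordinates at serial {line[6:11].strip()}")
            serial += 1
            records.append(
                AtomRecord(
                    serial=serial,
                    atom_name=atom_name,
                    residue_name=resname,
                    chain_id=chain,
                    residue_seq=resseq,
                    icode=icode,
                    position=xyz,
                )
            )
    if not records:
        raise EmptyStructureError(f"no standard-amino-acid ATOM records in {path}")
    return records


def coarse_grain(atoms: list[AtomRecord]) -> CGProtein:
    """One bead per residue at the residue's CA position; charge 0.

    Residues with no CA atom are dropped with a warning (chain breaks and
    partially modelled residues are common in deposited structures).
    """
    if not atoms:
        raise EmptyStructureError("no atoms to coarse-grain")
    beads: list[Bead] = []
    order: list[tuple] = []
    ca: dict[tuple, AtomRecord] = {}
    residues: set[tuple] = set()
    for a in atoms:
        rid = (a.chain_id, a.residue_seq, a.icode)
        if rid not in residues:
            residues.add(rid)
            order.append(rid)
        if a.atom_name == "CA" and rid not in ca:
            ca[rid] = a
    for i, rid in enumerate(order):
        a = ca.get(rid)
        if a is None:
            logger.warning("residue %s has no CA atom; dropped", rid)
            continue
        beads.append(
            Bead(
                index=len(beads),
                residue_name=a.residue_name,
                chain_id=a.chain_id,
                residue_seq=a.residue_seq,
                icode=a.icode,
                position=a.position.copy(),
            )
        )
    if not beads:
        raise EmptyStructureError("no residue has a CA atom")
    return CGProtein(beads=beads)


def _gyration_tensor(pos: np.ndarray) -> np.ndarray:
    c = pos.mean(axis=0)
    d = pos - c
    return d.T @ d / len(d)


def canonicalize(protein: CGProtein, weights: np.ndarray | None = None,
                 largest_extent_to_z: bool = True) -> CGProtein:
    """Centre the bead cloud and align principal axes (largest extent -> z).

    Unit bead masses by default; pass per-bead ``weights`` (e.g. residue
    masses) for a mass-weighted centroid and gyration tensor.
    ``largest_extent_to_z=False`` selects the alternative convention that
    puts the axis of largest moment of inertia (= smallest extent) on z.
    The rotation is proper (det +1); axis signs are fixed so the bead
    farthest from the centroid has non-negative z, then non-negative y.
    Degenerate (coincident-bead) inputs are only translated.
    """
    pos = protein.positions()
    if weights is None:
        w = np.full(len(pos), 1.0 / len(pos))
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    c = w @ pos
    pos = pos - c
    gyr = (pos * w[:, None]).T @ pos
    evals, evecs = np.linalg.eigh(gyr)  # ascending eigenvalues
    if evals[-1] < 1e-18:
        warnings.warn("degenerate bead cloud; translation-only canonicalization")
        return protein.with_positions(pos)
    if not largest_extent_to_z:
        evecs = evecs[:, ::-1]
    # columns: x <- smallest extent, y <- middle, z <- largest
    x_ax, y_ax, z_ax = evecs[:, 0], evecs[:, 1], evecs[:, 2]
    far = pos[np.argmax(np.linalg.norm(pos, axis=1))]
    if far @ z_ax < 0:
        z_ax = -z_ax
    if far @ y_ax < 0:
        y_ax = -y_ax
    x_ax = np.cross(y_ax, z_ax)  # right-handed, det +1
    rot = np.column_stack([x_ax, y_ax, z_ax])  # world -> canonical: p' = rot.T @ p
    return protein.with_positions(pos @ rot)


def orientation_matrix(o: Orientation) -> np.ndarray:
    """Rotation matrix R_y(180deg - theta) @ R_z(-phi).

    Maps the canonical-frame unit vector with polar angle theta and azimuth
    phi onto (0, 0, -1), i.e. toward a nanoparticle centred below the
    protein on the z-axis.
    """
    phi = np.deg2rad(o.phi)
    alpha = np.deg2rad(180.0 - o.theta)
    cz, sz = np.cos(-phi), np.sin(-phi)
    rz = np.array([[cz, -sz, 0.0], [sz, cz, 0.0], [0.0, 0.0, 1.0]])
    cy, sy = np.cos(alpha), np.sin(alpha)
    ry = np.array([[cy, 0.0, sy], [0.0, 1.0, 0.0], [-sy, 0.0, cy]])
    return ry @ rz


def orient(protein: CGProtein, o: Orientation) -> np.ndarray:
    """Bead positions after the rigid rotation for heatmap coordinates (phi, theta)."""
    return protein.positions() @ orientation_matrix(o).T
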