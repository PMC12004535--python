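"""Protein-nanoparticle interaction energies.

The total energy is pairwise additive over coarse-grained residue beads.
Each bead at surface separation h = d - R_NP (d the distance from the
nanoparticle centre to the bead) contributes three terms:

* screened electrostatics of the bead charge in the Debye-Hueckel
  potential outside a uniformly charged sphere at surface potential
  zeta:  U_el = q F zeta (R/(R+h)) exp(-kappa h);
* the tabulated short-range surface PMF for the bead's residue type,
  active below its grid range's end;
* the Hamaker two-sphere van der Waals attraction to the particle core,
  switched on beyond the cutoff r_cutoff (the PMF already contains the
  dispersion interaction at short range) with a constant offset making
  the total continuous at the splice.

A bead that would sit inside the particle (h < 0) marks the configuration
as a hard overlap: the total energy is +inf and the configuration gets
zero Boltzmann weight downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import EPS0, E_CHARGE, F_MV, KB_J, MOLAR_TO_NM3
from .materials import MaterialDB, pmf_value
from .structures import CGProtein

__all__ = [
    "Environment",
    "NanoparticleSpec",
    "ScreeningParams",
    "bjerrum_length",
    "debye_kappa",
    "electrostatic_energy",
    "hamaker_core_energy",
    "bead_energy",
    "protein_np_energy",
    "profile_energies",
    "DEFAULT_BEAD_RADIUS",
]

#: Effective residue-bead radius for the Hamaker core term, nm.
DEFAULT_BEAD_RADIUS = 0.5


@dataclass(frozen=True)
class Environment:
    """Solvent conditions: temperature (K), ionic strength (mol/L), pH, dielectric."""

    T: float = 309.75
    I: float = 0.15
    pH: float = 7.0
    eps_r: float = 78.4

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.I < 0:
            raise ValueError("ionic strength must be non-negative")


@dataclass(frozen=True)
class NanoparticleSpec:
    """Spherical nanoparticle: radius (nm), surface potential zeta (mV), material."""

    R_NP: float
    zeta: float
    material_id: str
    hkl: str = "000"

    def __post_init__(self) -> None:
        if self.R_NP <= 0:
            raise ValueError("nanoparticle radius must be positive")


@dataclass(frozen=True)
class ScreeningParams:
    l_B: float  # Bjerrum length, nm
    lambda_D: float  # Debye length, nm (inf when I = 0)
    kappa: float  # inverse Debye length, nm^-1


def bjerrum_length(env: Environment) -> float:
    """l_B = e^2 / (4 pi eps_r eps0 k_B T), in nm."""
    lb_m = E_CHARGE**2 / (4.0 * math.pi * env.eps_r * EPS0 * KB_J * env.T)
    return lb_m * 1e9


def debye_kappa(env: Environment) -> ScreeningParams:
    """Screening parameters for a 1:1 electrolyte: kappa = sqrt(8 pi l_B n)."""
    lb = bjerrum_length(env)
    if env.I == 0.0:
        return ScreeningParams(l_B=lb, lambda_D=math.inf, kappa=0.0)
    n = env.I * MOLAR_TO_NM3  # number density of each ion species, nm^-3
    kappa = math.sqrt(8.0 * math.pi * lb * n)
    return ScreeningParams(l_B=lb, lambda_D=1.0 / kappa, kappa=kappa)


def electrostatic_energy(q, h, np_spec: NanoparticleSpec, scr: ScreeningParams,
                         spherical: bool = True):
    """Screened-Coulomb energy of charge q (e) at surface separation h (nm), kJ/mol.

    ``spherical`` applies the linearized-PB geometric factor R/(R+h) of a
    sphere; disabling it gives the flat-surface exponential form.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("separation h must be >= 0")
    geom = np_spec.R_NP / (np_spec.R_NP + h) if spherical else 1.0
    return q * F_MV * np_spec.zeta * geom * np.exp(-scr.kappa * h)


def hamaker_core_energy(A, R_NP: float, r_bead: float, h):
    """Hamaker two-sphere van der Waals energy, kJ/mol.

    Centre separation d = R_NP + r_bead + h; requires h > 0 (surfaces not
    in contact).  A is the Hamaker constant in kJ/mol.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0):
        raise ValueError("Hamaker core term requires h > 0")
    d2 = (R_NP + r_bead + h) ** 2
    s_plus = (R_NP + r_bead) ** 2
    s_minus = (R_NP - r_bead) ** 2
    t1 = 2.0 * R_NP * r_bead / (d2 - s_plus)
    t2 = 2.0 * R_NP * r_bead / (d2 - s_minus)
    return -(np.asarray(A, dtype=float) / 6.0) * (t1 + t2 + np.log((d2 - s_plus) / (d2 - s_minus)))


def _core_term(A, np_spec: NanoparticleSpec, r_cutoff: float, h, r_bead: float):
    """Switched + offset Hamaker core contribution: 0 below r_cutoff, continuous at it."""
    scalar = np.ndim(h) == 0
    h = np.atleast_1d(np.asarray(h, dtype=float))
    u = np.zeros_like(h)
    beyond = h >= r_cutoff
    if np.any(beyond):
        offset = hamaker_core_energy(A, np_spec.R_NP, r_bead, r_cutoff)
        u[beyond] = hamaker_core_energy(A, np_spec.R_NP, r_bead, h[beyond]) - offset
    return float(u[0]) if scalar else u


def bead_energy(bead, h, np_spec: NanoparticleSpec, mat: MaterialDB, scr: ScreeningParams,
                r_bead: float = DEFAULT_BEAD_RADIUS, spherical: bool = True) -> float:
    """Total single-bead energy at surface separation h (nm), kJ/mol."""
    res = bead.residue_name
    if res not in mat.pmf or res not in mat.hamaker:
        raise KeyError(f"residue {res} not parameterised in material {mat.material_id}")
    u_el = electrostatic_energy(bead.charge, h, np_spec, scr, spherical=spherical)
    u_s = pmf_value(mat.pmf[res], h)
    u_c = _core_term(mat.hamaker[res], np_spec, mat.r_cutoff, h, r_bead)
    return float(u_el) + float(u_s) + float(u_c)


def protein_np_energy(protein: CGProtein, z: float, np_spec: NanoparticleSpec,
                      mat: MaterialDB, scr: ScreeningParams,
                      positions: np.ndarray | None = None,
                      r_bead: float = DEFAULT_BEAD_RADIUS, spherical: bool = True) -> float:
    """Total energy with the protein COM at (0, 0, z), NP centred at the origin.

    ``positions`` (already-oriented bead coordinates, centroid at origin)
    defaults to the protein's stored coordinates.  Returns +inf if any bead
    lies inside the particle.
    """
    pos = protein.positions() if positions is None else np.asarray(positions, dtype=float)
    u, _ = profile_energies(
        pos, protein.residue_names(), protein.charges(), np.array([z]),
        np_spec, mat, scr, r_bead=r_bead, spherical=spherical,
    )
    return float(u[0])


def profile_energies(positions: np.ndarray, residues: list[str], charges: np.ndarray,
                     z_values: np.ndarray, np_spec: NanoparticleSpec, mat: MaterialDB,
                     scr: ScreeningParams, r_bead: float = DEFAULT_BEAD_RADIUS,
                     spherical: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised total energy along a z-scan.

    Returns ``(U, h_min)``: for each COM height z in ``z_values``, the total
    protein energy (kJ/mol, +inf on overlap) and the minimum bead-surface
    separation (nm).  This is the hot loop of the orientation scan: the
    (n_z, n_bead) separation matrix is built once and every term is
    evaluated on it per residue type.
    """
    pos = np.asarray(positions, dtype=float)
    z_values = np.asarray(z_values, dtype=float)
    rho2 = pos[:, 0] ** 2 + pos[:, 1] ** 2
    # d[j, i]: centre distance of bead i at scan height z_j
    d = np.sqrt(rho2[None, :] + (pos[None, :, 2] + z_values[:, None]) ** 2)
    h = d - np_spec.R_NP
    h_min = h.min(axis=1)
    overlap = h_min < -1e-9  # below roundoff of the exact-contact start point

    u = np.zeros_like(h)
    h_safe = np.clip(h, 0.0, None)
    # electrostatics: same functional form for all beads, linear in q
    geom = np_spec.R_NP / (np_spec.R_NP + h_safe) if spherical else 1.0
    u += charges[None, :] * (F_MV * np_spec.zeta) * geom * np.exp(-scr.kappa * h_safe)
    # PMF + Hamaker, grouped by residue type
    res_arr = np.asarray(residues)
    for res in np.unique(res_arr):
        cols = res_arr == res
        hh = h_safe[:, cols]
        u_res = pmf_value(mat.pmf[res], hh.ravel()).reshape(hh.shape)
        A = mat.hamaker[res]
        beyond = hh >= mat.r_cutoff
        if np.any(beyond):
            offset = hamaker_core_energy(A, np_spec.R_NP, r_bead, mat.r_cutoff)
            u_res[beyond] += hamaker_core_energy(A, np_spec.R_NP, r_bead, hh[beyond]) - offset
        u[:, cols] += u_res
    total = u.sum(axis=1)
    total[overlap] = np.inf
    return total, h_min
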