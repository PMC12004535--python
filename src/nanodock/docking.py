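"""Orientation scan, Boltzmann averaging and pose selection.

Adsorption is modelled as the rigid protein approaching the nanoparticle
along the z-axis at a fixed orientation (phi, theta).  For each orientation
the energy is evaluated on a ladder of separations from closest-bead
contact (h = 0) out to h_max, and collapsed to a single orientation energy
by a Boltzmann average over the ladder.  Orientations are sampled within
each delta x delta angular bin (n_bin random draws, or the bin centre);
the per-bin mean and sample standard deviation populate the heatmap.

The global adsorption energy E_ads is the Boltzmann-weighted average of
the per-bin energies over the whole (phi, theta) grid, with the sin(theta)
area element so that weighting is uniform over orientations on the sphere.
Candidate docking poses are the local minima of the heatmap lying within
one standard deviation of the absolute minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB_KJMOL
from .energy import (
    DEFAULT_BEAD_RADIUS,
    MaterialDB,
    NanoparticleSpec,
    ScreeningParams,
    profile_energies,
)
from .structures import CGProtein, Orientation, orient

__all__ = [
    "ScanConfig",
    "EnergyMap",
    "DockResult",
    "contact_z",
    "distance_profile",
    "boltzmann_mean",
    "orientation_scan",
    "adsorption_energy",
    "candidate_minima",
    "dock",
    "build_pose",
]


@dataclass(frozen=True)
class ScanConfig:
    """Resolution and sampling settings for the orientation scan.

    delta: angular bin width in degrees (must divide 360 and 180).
    n_bin: orientation samples per bin.
    n_total_cap: hard cap on (360/delta)(180/delta)*n_bin profile evaluations.
    h_max: closest-bead separation window, nm.
    dz: separation step, nm.
    sample_mode: "random" draws within each bin, "center" uses bin centres.
    """

    delta: float = 5.0
    n_bin: int = 6
    n_total_cap: int = 16200
    h_max: float = 2.0
    dz: float = 0.05
    seed: int = 0
    sample_mode: str = "random"
    free_energy: bool = False  # per-orientation -kT ln Z instead of mean energy
    sin_theta_weight: bool = True

    def __post_init__(self) -> None:
        if self.delta <= 0 or abs(360.0 / self.delta - round(360.0 / self.delta)) > 1e-9 \
                or abs(180.0 / self.delta - round(180.0 / self.delta)) > 1e-9:
            raise ValueError(f"delta must divide 360 and 180: {self.delta}")
        if self.n_bin < 1:
            raise ValueError("n_bin must be >= 1")
        if self.sample_mode not in ("random", "center"):
            raise ValueError(f"unknown sample_mode: {self.sample_mode}")
        if self.n_evaluations >= self.n_total_cap:
            raise ValueError(
                f"(360/delta)*(180/delta)*n_bin = {self.n_evaluations} "
                f"exceeds the cap {self.n_total_cap}"
            )

    @property
    def n_phi(self) -> int:
        return int(round(360.0 / self.delta))

    @property
    def n_theta(self) -> int:
        return int(round(180.0 / self.delta))

    @property
    def n_evaluations(self) -> int:
        """Total distance-profile evaluations the scan will perform."""
        return self.n_phi * self.n_theta * self.n_bin


@dataclass
class EnergyMap:
    """Per-orientation-bin heatmap of Boltzmann-mean energies.

    Arrays are (n_theta, n_phi); ``phi``/``theta`` hold the lower bin edges.
    """

    phi: np.ndarray
    theta: np.ndarray
    E: np.ndarray
    sd: np.ndarray
    min_dist: np.ndarray
    T: float
    config: ScanConfig
    n_evaluations: int = 0

    def min_bin(self) -> tuple[int, int]:
        """(k, l) indices of the absolute-minimum bin; ties -> lowest theta, then phi."""
        k, l = np.unravel_index(np.argmin(self.E, axis=None), self.E.shape)
        return int(k), int(l)


@dataclass
class DockResult:
    e_ads: float
    e_min: float
    sd_at_min: float
    min_orientation: Orientation
    threshold: float
    candidates: list[tuple[Orientation, float]] = field(default_factory=list)
    pose_z: float = 0.0
    at_window_edge: bool = False


def contact_z(positions: np.ndarray, R_NP: float) -> float:
    """COM height z0 at which the closest bead touches the sphere (min_i h_i = 0).

    For each bead with cylindrical radius rho <= R the touching height is
    -p_z + sqrt(R^2 - rho^2); the contact height is the largest of these.
    If every bead passes outside the sphere the closest approach over z is
    returned instead (min_i h_i minimised, not zero).
    """
    pos = np.asarray(positions, dtype=float)
    rho2 = pos[:, 0] ** 2 + pos[:, 1] ** 2
    inside = rho2 <= R_NP**2
    if np.any(inside):
        z_touch = -pos[inside, 2] + np.sqrt(R_NP**2 - rho2[inside])
        return float(z_touch.max())
    # closest pass: each bead's h is minimised at z = -p_z; take the best bead
    i = int(np.argmin(np.sqrt(rho2) - R_NP))
    return float(-pos[i, 2])


def distance_profile(protein: CGProtein, o: Orientation, np_spec: NanoparticleSpec,
                     mat: MaterialDB, scr: ScreeningParams, cfg: ScanConfig,
                     r_bead: float = DEFAULT_BEAD_RADIUS,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Energy ladder for one orientation: returns (z, U, h_min) arrays.

    The ladder starts at closest-bead contact z0 and climbs in steps of dz
    until the closest bead is h_max from the surface.
    """
    pos = orient(protein, o)
    return _profile_at(pos, protein, np_spec, mat, scr, cfg, r_bead)


def _profile_at(pos: np.ndarray, protein: CGProtein, np_spec: NanoparticleSpec,
                mat: MaterialDB, scr: ScreeningParams, cfg: ScanConfig,
                r_bead: float = DEFAULT_BEAD_RADIUS,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    z0 = contact_z(pos, np_spec.R_NP)
    n_steps = int(np.ceil(cfg.h_max / cfg.dz))
    z = z0 + cfg.dz * np.arange(n_steps + 1)
    u, h_min = profile_energies(
        pos, protein.residue_names(), protein.charges(), z, np_spec, mat, scr, r_bead=r_bead,
    )
    return z, u, h_min


def boltzmann_mean(U, T: float) -> float:
    """Boltzmann-average energy of a ladder of states, kJ/mol.

    E = sum U_j w_j / sum w_j with w_j = exp(-U_j / kT), computed with a
    min-shift for numerical stability; +inf entries (hard overlaps) carry
    zero weight.  Raises if every entry is +inf.
    """
    u = np.asarray(U, dtype=float)
    if u.size == 0:
        raise ValueError("empty energy ladder")
    finite = np.isfinite(u)
    if not np.any(finite):
        raise ValueError("no admissible separation: all energies are +inf")
    uf = u[finite]
    kt = KB_KJMOL * T
    shift = uf.min()
    w = np.exp(-(uf - shift) / kt)
    return float(np.sum(uf * w) / np.sum(w))


def _free_energy(U, T: float) -> float:
    """Per-orientation free energy -kT ln <exp(-U/kT)> over the ladder."""
    u = np.asarray(U, dtype=float)
    finite = np.isfinite(u)
    if not np.any(finite):
        raise ValueError("no admissible separation: all energies are +inf")
    uf = u[finite]
    kt = KB_KJMOL * T
    shift = uf.min()
    return float(shift - kt * np.log(np.mean(np.exp(-(uf - shift) / kt))))


def orientation_scan(protein: CGProtein, np_spec: NanoparticleSpec, mat: MaterialDB,
                     scr: ScreeningParams, cfg: ScanConfig, T: float,
                     r_bead: float = DEFAULT_BEAD_RADIUS) -> EnergyMap:
    """Scan every (phi, theta) bin and build the orientation-energy heatmap.

    Per bin: n_bin orientations (seeded-random within the bin, or the bin
    centre), each collapsed to one energy by the ladder Boltzmann average;
    the bin stores their arithmetic mean, sample SD (ddof=1; 0 for a single
    sample) and the smallest closest-approach distance at which any
    sample's ladder attains its energy minimum.
    """
    rng = np.random.default_rng(cfg.seed)
    phis = np.arange(cfg.n_phi) * cfg.delta
    thetas = np.arange(cfg.n_theta) * cfg.delta
    E = np.empty((cfg.n_theta, cfg.n_phi))
    sd = np.zeros_like(E)
    min_dist = np.empty_like(E)
    reducer = _free_energy if cfg.free_energy else boltzmann_mean
    n_eval = 0
    for k, th in enumerate(thetas):
        for l, ph in enumerate(phis):
            samples = np.empty(cfg.n_bin)
            dists = np.empty(cfg.n_bin)
            for s in range(cfg.n_bin):
                if cfg.sample_mode == "center":
                    o = Orientation(phi=ph + cfg.delta / 2.0, theta=th + cfg.delta / 2.0)
                else:
                    o = Orientation(
                        phi=ph + cfg.delta * rng.random(),
                        theta=th + cfg.delta * rng.random(),
                    )
                _, u, h_min = distance_profile(protein, o, np_spec, mat, scr, cfg, r_bead)
                n_eval += 1
                samples[s] = reducer(u, T)
                finite = np.isfinite(u)
                j = int(np.flatnonzero(finite)[np.argmin(u[finite])])
                dists[s] = h_min[j]
            E[k, l] = samples.mean()
            sd[k, l] = samples.std(ddof=1) if cfg.n_bin > 1 else 0.0
            min_dist[k, l] = dists.min()
    return EnergyMap(phi=phis, theta=thetas, E=E, sd=sd, min_dist=min_dist,
                     T=T, config=cfg, n_evaluations=n_eval)


def adsorption_energy(emap: EnergyMap, T: float | None = None) -> float:
    """Global Boltzmann-weighted adsorption energy E_ads over all bins, kJ/mol.

    Weights P_kl ~ sin(theta_k + delta/2) exp(-E_kl / kT) (the sin factor
    is the spherical area element; disabled via the scan config's
    ``sin_theta_weight`` for strict grid averaging), normalised to 1.
    """
    T = emap.T if T is None else T
    kt = KB_KJMOL * T
    shift = emap.E.min()
    w = np.exp(-(emap.E - shift) / kt)
    if emap.config.sin_theta_weight:
        half = emap.config.delta / 2.0
        w = w * np.sin(np.deg2rad(emap.theta + half))[:, None]
    return float(np.sum(w * emap.E) / np.sum(w))


def _local_minima(E: np.ndarray) -> np.ndarray:
    """Boolean mask of 8-neighbourhood local minima; periodic in phi only."""
    n_t, n_p = E.shape
    mask = np.ones_like(E, dtype=bool)
    for dk in (-1, 0, 1):
        for dl in (-1, 0, 1):
            if dk == 0 and dl == 0:
                continue
            shifted = np.roll(E, -dl, axis=1)  # phi periodic
            if dk == -1:
                nbr = np.vstack([np.full((1, n_p), np.inf), shifted[:-1]])
            elif dk == 1:
                nbr = np.vstack([shifted[1:], np.full((1, n_p), np.inf)])
            else:
                nbr = shifted
            mask &= E <= nbr
    return mask


def candidate_minima(emap: EnergyMap) -> DockResult:
    """Absolute minimum, its SD, and all candidate docking orientations.

    Candidates are grid local minima (8-neighbourhood, periodic in phi)
    whose energy lies within one standard deviation of the absolute
    minimum (E <= e_min + sd_at_min), sorted by energy; exact ties are
    ordered by (theta, phi).
    """
    k0, l0 = emap.min_bin()
    e_min = float(emap.E[k0, l0])
    sd_min = float(emap.sd[k0, l0])
    threshold = e_min + sd_min
    mask = _local_minima(emap.E) & (emap.E <= threshold)
    mask[k0, l0] = True
    ks, ls = np.nonzero(mask)
    order = sorted(
        range(len(ks)),
        key=lambda i: (emap.E[ks[i], ls[i]], emap.theta[ks[i]], emap.phi[ls[i]]),
    )
    candidates = [
        (Orientation(phi=float(emap.phi[ls[i]]), theta=float(emap.theta[ks[i]])),
         float(emap.E[ks[i], ls[i]]))
        for i in order
    ]
    return DockResult(
        e_ads=adsorption_energy(emap),
        e_min=e_min,
        sd_at_min=sd_min,
        min_orientation=Orientation(phi=float(emap.phi[l0]), theta=float(emap.theta[k0])),
        threshold=threshold,
        candidates=candidates,
    )


def dock(protein: CGProtein, np_spec: NanoparticleSpec, mat: MaterialDB,
         scr: ScreeningParams, cfg: ScanConfig, T: float) -> tuple[EnergyMap, DockResult]:
    """Full docking run: orientation scan + heatmap statistics + candidates."""
    emap = orientation_scan(protein, np_spec, mat, scr, cfg, T)
    return emap, candidate_minima(emap)


def build_pose(protein: CGProtein, o: Orientation, np_spec: NanoparticleSpec,
               mat: MaterialDB, scr: ScreeningParams, cfg: ScanConfig,
               ) -> tuple[np.ndarray, float, bool]:
    """Docked coordinates for one orientation.

    Returns (positions, z_star, at_edge): bead positions oriented at
    (phi, theta) and translated so the COM sits at (0, 0, z_star), the
    separation of minimum ladder energy; ``at_edge`` flags a purely
    repulsive profile whose minimum lies at the window boundary.
    """
    pos = orient(protein, o)
    z, u, _ = _profile_at(pos, protein, np_spec, mat, scr, cfg)
    finite = np.isfinite(u)
    j = int(np.flatnonzero(finite)[np.argmin(u[finite])])
    z_star = float(z[j])
    at_edge = j == len(z) - 1
    return pos + np.array([0.0, 0.0, z_star]), z_star, at_edge
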