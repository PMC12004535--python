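"""Result writers: UAM table, heatmap PNG, docked pose PDB/XYZ, Hamaker
material.dat, and a key-value CONFIG file for downstream desktop runs.

The UAM file is the tabular companion of the heatmap: one row per
(phi, theta) bin with the Boltzmann-mean adsorption energy, its standard
deviation over the bin's orientation samples, and the minimum bead-surface
distance.  Formatting is canonical (fixed width, energies to 0.01 kJ/mol)
so that write -> read -> write is byte-identical.
"""

from __future__ import annotations

import numpy as np

from .docking import DockResult, EnergyMap, ScanConfig
from .energy import Environment, NanoparticleSpec
from .structures import CGProtein, Orientation

__all__ = [
    "write_uam",
    "read_uam",
    "write_heatmap",
    "write_pose",
    "write_config",
    "read_config",
]

_UAM_HEADER = "#   phi     theta          Eads    SDEV(Eads)       MinDist"


def write_uam(emap: EnergyMap, path) -> None:
    """Write the per-bin table, theta-major then phi, energies to 0.01 kJ/mol."""
    if emap.E.size == 0:
        raise ValueError("empty energy map")
    lines = [
        f"# orientation-energy map: delta={emap.config.delta:g} deg, "
        f"n_bin={emap.config.n_bin}, seed={emap.config.seed}, "
        f"sample_mode={emap.config.sample_mode}, T={emap.T:g} K",
        _UAM_HEADER,
    ]
    for k in range(len(emap.theta)):
        for l in range(len(emap.phi)):
            lines.append(
                f"{emap.phi[l]:7.2f} {emap.theta[k]:9.2f} "
                f"{emap.E[k, l]:13.2f} {emap.sd[k, l]:13.2f} {emap.min_dist[k, l]:13.3f}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_uam(path) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Read a UAM file back: (phi, theta, E, sd, min_dist) grid arrays."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    phis = np.unique(data[:, 0])
    thetas = np.unique(data[:, 1])
    shape = (len(thetas), len(phis))
    return (phis, thetas, data[:, 2].reshape(shape), data[:, 3].reshape(shape),
            data[:, 4].reshape(shape))


def write_heatmap(emap: EnergyMap, path, result: DockResult | None = None) -> None:
    """Render the orientation-energy heatmap to a PNG.

    phi on x (0-360 deg), theta on y (0-180 deg), colour = Boltzmann-mean
    energy in kJ/mol; candidate docking orientations are overplotted as
    stars when a DockResult is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = emap.config.delta
    fig, ax = plt.subplots(figsize=(8, 4.2))
    mesh = ax.pcolormesh(
        np.append(emap.phi, 360.0), np.append(emap.theta, 180.0), emap.E,
        cmap="viridis", shading="flat",
    )
    fig.colorbar(mesh, ax=ax, label="E (kJ/mol)")
    if result is not None:
        for o, _ in result.candidates:
            ax.plot(o.phi + d / 2, o.theta + d / 2, marker="*", ms=12,
                    mfc="white", mec="black")
    ax.set_xlim(0.0, 360.0)
    ax.set_ylim(0.0, 180.0)
    ax.set_xlabel(r"$\phi$ (deg)")
    ax.set_ylabel(r"$\theta$ (deg)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_pose(protein: CGProtein, positions: np.ndarray, z_star: float,
               np_spec: NanoparticleSpec, path_pdb, path_xyz,
               orientation: Orientation | None = None) -> None:
    """Write the docked pose as a CA-only PDB and an XYZ file.

    Coordinates are emitted in Angstrom with the nanoparticle centre at the
    origin (recorded in a REMARK with the radius); each bead becomes one CA
    atom of its residue.  The XYZ comment line records phi, theta and z.
    """
    pos = np.asarray(positions, dtype=float)
    o = orientation
    with open(path_pdb, "w") as fh:
        fh.write(f"REMARK   NP centre at origin, radius {np_spec.R_NP:.3f} nm"
                 f" ({np_spec.material_id} hkl={np_spec.hkl})\n")
        if o is not None:
            fh.write(f"REMARK   orientation phi={o.phi:.2f} theta={o.theta:.2f}"
                     f" z={z_star:.4f} nm\n")
        for b, p in zip(protein.beads, pos):
            x, y, z = p * 10.0  # nm -> Angstrom
            fh.write(
                f"ATOM  {b.index + 1:5d}  CA  {b.residue_name:>3s} {b.chain_id}"
                f"{b.residue_seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                f"           C\n"
            )
        fh.write("END\n")
    with open(path_xyz, "w") as fh:
        fh.write(f"{len(protein.beads)}\n")
        head = f"phi={o.phi:.2f} theta={o.theta:.2f} " if o is not None else ""
        fh.write(f"{head}z={z_star:.4f} nm; coordinates in Angstrom\n")
        for p in pos:
            x, y, z = p * 10.0
            fh.write(f"C {x:.3f} {y:.3f} {z:.3f}\n")


def write_config(path, pdb_name: str, np_spec: NanoparticleSpec, env: Environment,
                 cfg: ScanConfig) -> None:
    """Write the run parameters as a 'key: value' file (best-effort
    compatibility with downstream desktop tooling)."""
    items = {
        "pdb": pdb_name,
        "material": np_spec.material_id,
        "hkl": np_spec.hkl,
        "radius-nm": np_spec.R_NP,
        "zeta-mv": np_spec.zeta,
        "temperature-k": env.T,
        "ionic-strength-m": env.I,
        "ph": env.pH,
        "delta": cfg.delta,
        "n-bin": cfg.n_bin,
        "seed": cfg.seed,
    }
    with open(path, "w") as fh:
        for key, value in items.items():
            fh.write(f"{key}: {value!r}\n" if isinstance(value, str) else f"{key}: {value}\n")


def read_config(path) -> dict[str, str]:
    """Parse a 'key: value' CONFIG file into a string map."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition(":")
            out[key.strip()] = value.strip().strip("'")
    return out


def write_material_dat(mat, path) -> None:
    """Write the Hamaker-constant table alone (material.dat dialect)."""
    with open(path, "w") as fh:
        fh.write(f"# Hamaker constants (kJ/mol) for {mat.material_id} hkl={mat.hkl}\n")
        for aa in sorted(mat.hamaker):
            fh.write(f"{aa} {mat.hamaker[aa]:.17g}\n")

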