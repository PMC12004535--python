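"""Orientation scan, Boltzmann statistics, candidate selection, poses."""

import math
import time

import numpy as np
import pytest

from nanodock.constants import KB_KJMOL
from nanodock.docking import (
    EnergyMap,
    ScanConfig,
    adsorption_energy,
    boltzmann_mean,
    build_pose,
    candidate_minima,
    contact_z,
    distance_profile,
    dock,
    orientation_scan,
)
from nanodock.energy import Environment, NanoparticleSpec, debye_kappa
from nanodock.structures import Orientation, canonicalize, orient

import oracles
from conftest import make_protein


def _uniform_map(c, delta=45.0, sd=0.0):
    n_t, n_p = int(180 / delta), int(360 / delta)
    cfg = ScanConfig(delta=delta, n_bin=1, seed=0)
    return EnergyMap(
        phi=np.arange(n_p) * delta, theta=np.arange(n_t) * delta,
        E=np.full((n_t, n_p), float(c)), sd=np.full((n_t, n_p), float(sd)),
        min_dist=np.zeros((n_t, n_p)), T=309.75, config=cfg,
    )


# ---------------------------------------------------------------- ScanConfig

def test_scan_config_cap_and_divisibility():
    cfg = ScanConfig()  # stock defaults
    assert cfg.n_evaluations == 72 * 36 * 6 == 15552
    assert cfg.n_evaluations < cfg.n_total_cap
    with pytest.raises(ValueError, match="divide"):
        ScanConfig(delta=7.0)
    with pytest.raises(ValueError, match="cap"):
        ScanConfig(delta=5.0, n_bin=7)


# ------------------------------------------------------------ distance scan

def test_contact_z_single_bead(np_spec, material, screening):
    prot = make_protein([[0.0, 0.0, 0.0]], ["GLY"])
    cfg = ScanConfig(delta=45.0, n_bin=1)
    z, u, h_min = distance_profile(
        prot, Orientation(phi=0, theta=0), np_spec, material, screening, cfg
    )
    assert z[0] == pytest.approx(np_spec.R_NP)
    np.testing.assert_allclose(h_min, cfg.dz * np.arange(len(z)), atol=1e-12)


def test_contact_z_matches_bisection_oracle(np_spec):
    rng = np.random.default_rng(21)
    pos = rng.normal(scale=0.6, size=(5, 3))
    prot = canonicalize(make_protein(pos))
    for phi, theta in [(0, 0), (120, 45), (275, 160)]:
        rotated = orient(prot, Orientation(phi=phi, theta=theta))
        z0 = contact_z(rotated, np_spec.R_NP)
        ref = oracles.contact_z_bisect([tuple(p) for p in rotated], np_spec.R_NP)
        assert z0 == pytest.approx(ref, abs=1e-6)


def test_profile_tail_is_zero_for_neutral_protein(np_spec, zero_material, screening):
    """Beyond the PMF range a chargeless, vdW-free protein feels nothing."""
    prot = make_protein([[0, 0, 0]], ["GLY"])
    cfg = ScanConfig(delta=45.0, n_bin=1)
    _, u, _ = distance_profile(
        prot, Orientation(phi=0, theta=0), np_spec, zero_material, screening, cfg
    )
    assert u[-1] == 0.0


# --------------------------------------------------------- Boltzmann means

def test_boltzmann_mean_constant_profile():
    assert boltzmann_mean([3.3] * 7, 309.75) == pytest.approx(3.3)


def test_boltzmann_mean_high_T_limit():
    u = 5.0
    assert boltzmann_mean([0.0, u], 1e9) == pytest.approx(u / 2, rel=1e-6)


def test_boltzmann_mean_matches_direct_sum():
    us = [-10.0, 0.0, 10.0]
    T = 309.75
    ref = oracles.boltzmann_mean_direct(us, T)
    assert boltzmann_mean(us, T) == pytest.approx(ref, rel=1e-12)
    # explicit kT evaluation from the molar gas constant
    assert KB_KJMOL * T == pytest.approx(2.5754, abs=1e-3)


def test_boltzmann_mean_infinities():
    assert boltzmann_mean([math.inf, -5.0, math.inf], 300.0) == pytest.approx(-5.0)
    with pytest.raises(ValueError):
        boltzmann_mean([math.inf, math.inf], 300.0)
    with pytest.raises(ValueError):
        boltzmann_mean([], 300.0)


def test_boltzmann_mean_deep_well_stability():
    """min-shift keeps very deep wells finite (naive exp would overflow)."""
    assert boltzmann_mean([-5000.0, 0.0], 309.75) == pytest.approx(-5000.0)


# ---------------------------------------------------------------- the scan

def test_scan_bin_counts_and_determinism(helix_protein, np_spec, material, screening):
    cfg = ScanConfig(delta=45.0, n_bin=2, seed=42)
    m1 = orientation_scan(helix_protein, np_spec, material, screening, cfg, 309.75)
    assert m1.E.shape == (4, 8)
    assert m1.n_evaluations == 4 * 8 * 2
    m2 = orientation_scan(helix_protein, np_spec, material, screening, cfg, 309.75)
    np.testing.assert_array_equal(m1.E, m2.E)
    np.testing.assert_array_equal(m1.sd, m2.sd)
    m3 = orientation_scan(
        helix_protein, np_spec, material, screening,
        ScanConfig(delta=45.0, n_bin=2, seed=43), 309.75,
    )
    assert not np.array_equal(m1.E, m3.E)


def test_scan_single_sample_has_zero_sd(helix_protein, np_spec, material, screening):
    cfg = ScanConfig(delta=90.0, n_bin=1, seed=0)
    emap = orientation_scan(helix_protein, np_spec, material, screening, cfg, 309.75)
    np.testing.assert_array_equal(emap.sd, 0.0)


def test_scan_spherically_symmetric_protein_is_flat(np_spec, material, screening):
    """A single-bead 'protein' has no orientation dependence at all."""
    prot = make_protein([[0.0, 0.0, 0.0]], ["TRP"], charges=[0.3])
    cfg = ScanConfig(delta=45.0, n_bin=2, seed=3)
    emap = orientation_scan(prot, np_spec, material, screening, cfg, 309.75)
    np.testing.assert_allclose(emap.E, emap.E[0, 0], atol=1e-9)


# ------------------------------------------------------------------- E_ads

def test_adsorption_energy_uniform_map():
    assert adsorption_energy(_uniform_map(-7.5)) == pytest.approx(-7.5)


def test_adsorption_energy_boltzmann_dominance_at_low_T():
    emap = _uniform_map(0.0)
    emap.E[1, 2] = -100.0
    emap.T = 1e-3
    assert adsorption_energy(emap) == pytest.approx(-100.0)


def test_adsorption_energy_matches_direct_sum():
    rng = np.random.default_rng(8)
    emap = _uniform_map(0.0, delta=45.0)
    emap.E = rng.uniform(-30.0, 5.0, size=emap.E.shape)
    ref = oracles.e_ads_direct(emap.theta.tolist(), emap.phi.tolist(),
                               emap.E.tolist(), emap.T, 45.0)
    assert adsorption_energy(emap) == pytest.approx(ref, abs=1e-10)


def test_adsorption_energy_between_min_and_max():
    rng = np.random.default_rng(12)
    emap = _uniform_map(0.0)
    emap.E = rng.uniform(-50.0, 10.0, size=emap.E.shape)
    e = adsorption_energy(emap)
    assert emap.E.min() <= e <= emap.E.max()


# -------------------------------------------------------------- candidates

def test_candidate_threshold_rule():
    """threshold = e_min + sd_at_min applied to the heatmap minimum."""
    emap = _uniform_map(0.0, sd=0.0)
    emap.E[1, 3] = -185.91
    emap.sd[1, 3] = 4.45
    res = candidate_minima(emap)
    assert res.e_min == pytest.approx(-185.91)
    assert res.sd_at_min == pytest.approx(4.45)
    assert res.threshold == pytest.approx(-181.46)


def test_single_basin_single_candidate():
    emap = _uniform_map(0.0, delta=45.0)
    # one smooth basin centred on (theta=90, phi=180)
    for k, th in enumerate(emap.theta):
        for l, ph in enumerate(emap.phi):
            emap.E[k, l] = -40.0 + 0.002 * ((th - 90) ** 2 + (ph - 180) ** 2)
    emap.sd[:] = 1.0
    res = candidate_minima(emap)
    assert len(res.candidates) == 1
    assert res.candidates[0][0] == Orientation(phi=180.0, theta=90.0)


def test_equal_minima_tie_break():
    emap = _uniform_map(0.0, delta=45.0)
    emap.E[3, 1] = -20.0
    emap.E[1, 5] = -20.0
    res = candidate_minima(emap)
    assert [c[1] for c in res.candidates[:2]] == [-20.0, -20.0]
    # ties ordered by (theta, phi) ascending
    assert res.candidates[0][0].theta < res.candidates[1][0].theta
    assert res.min_orientation == res.candidates[0][0]


def test_candidates_respect_threshold():
    emap = _uniform_map(0.0, delta=45.0)
    emap.E[1, 1] = -50.0
    emap.sd[1, 1] = 5.0
    emap.E[2, 5] = -47.0  # within 1 SD: candidate
    emap.E[3, 3] = -40.0  # local minimum but above threshold
    res = candidate_minima(emap)
    energies = [e for _, e in res.candidates]
    assert -50.0 in energies and -47.0 in energies and -40.0 not in energies


# ------------------------------------------------------------------- poses

def test_build_pose_places_minimum(np_spec, material, screening):
    """Single bead: pose separation sits at the PMF minimum within dz."""
    prot = make_protein([[0.0, 0.0, 0.0]], ["TRP"])
    cfg = ScanConfig(delta=45.0, n_bin=1, dz=0.01)
    pos, z_star, at_edge = build_pose(
        prot, Orientation(phi=0, theta=90), np_spec, material, screening, cfg
    )
    assert not at_edge
    table = material.pmf["TRP"]
    h_star = table.h[np.argmin(table.u)]
    assert z_star - np_spec.R_NP == pytest.approx(h_star, abs=cfg.dz)
    np.testing.assert_allclose(pos, [[0, 0, z_star]])


def test_build_pose_repulsive_flags_edge(np_spec, zero_material, screening):
    prot = make_protein([[0.0, 0.0, 0.0]], ["GLY"], charges=[1.0])
    repel = NanoparticleSpec(R_NP=15.0, zeta=+40.0, material_id="TESTMAT")
    cfg = ScanConfig(delta=45.0, n_bin=1)
    _, z_star, at_edge = build_pose(
        prot, Orientation(phi=0, theta=0), repel, zero_material, screening, cfg
    )
    assert at_edge
    assert z_star == pytest.approx(repel.R_NP + cfg.h_max, abs=cfg.dz)


def test_build_pose_is_rigid(helix_protein, np_spec, material, screening):
    cfg = ScanConfig(delta=45.0, n_bin=1)
    pos, _, _ = build_pose(
        helix_protein, Orientation(phi=120, theta=60), np_spec, material, screening, cfg
    )
    d_in = np.linalg.norm(
        helix_protein.positions()[:, None] - helix_protein.positions()[None], axis=-1
    )
    d_out = np.linalg.norm(pos[:, None] - pos[None], axis=-1)
    np.testing.assert_allclose(d_out, d_in, atol=1e-9)


# -------------------------------------------------- full-pipeline oracle

def test_pipeline_matches_brute_force_oracle(material):
    """3-bead protein, delta=45, bin-centre sampling: full map and E_ads
    agree with the independent <100-line implementation."""
    env = Environment()
    scr = debye_kappa(env)
    np_spec = NanoparticleSpec(R_NP=15.0, zeta=-20.0, material_id="TESTMAT")
    residues = ["LYS", "GLY", "ASP"]
    charges = [1.0, 0.0, -1.0]
    prot = canonicalize(make_protein(
        [[0, 0, 0.0], [0.05, 0.02, 0.4], [0, 0, 0.8]], residues, charges
    ))
    cfg = ScanConfig(delta=45.0, n_bin=1, sample_mode="center", seed=0)
    emap, res = dock(prot, np_spec, material, scr, cfg, env.T)
    pmf = {aa: (material.pmf[aa].h.tolist(), material.pmf[aa].u.tolist())
           for aa in set(residues)}
    E_ref, e_ads_ref = oracles.brute_force_dock(
        [tuple(p) for p in prot.positions()], residues, charges,
        15.0, -20.0, scr.kappa, pmf, material.hamaker, material.r_cutoff, env.T,
        delta=45.0, h_max=cfg.h_max, dz=cfg.dz,
    )
    np.testing.assert_allclose(emap.E, np.array(E_ref), atol=1e-8)
    assert res.e_ads == pytest.approx(e_ads_ref, abs=1e-8)


def test_runtime_scales_linearly_in_residues(np_spec, material, screening):
    """One profile on 1000 beads costs at most ~linear over 100 beads."""
    rng = np.random.default_rng(0)
    cfg = ScanConfig(delta=45.0, n_bin=1)

    def profile_time(n):
        prot = make_protein(rng.normal(scale=1.5, size=(n, 3)))
        o = Orientation(phi=10.0, theta=80.0)
        distance_profile(prot, o, np_spec, material, screening, cfg)  # warm up
        t0 = time.perf_counter()
        for _ in range(20):
            distance_profile(prot, o, np_spec, material, screening, cfg)
        return time.perf_counter() - t0

    t100, t1000 = profile_time(100), profile_time(1000)
    assert t1000 / t100 < 25.0  # 10x residues, generously sub-quadratic
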