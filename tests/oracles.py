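"""Independent brute-force reference implementations used as test oracles.

Everything here is written with plain Python loops and math, deliberately
sharing no code with the package: linear interpolation by hand, explicit
rotation matrices, direct Boltzmann sums via math.fsum.
"""

from __future__ import annotations

import math

KB = 8.31446261815324e-3  # kJ/mol/K
F_MV = 0.09648533212331  # kJ/mol per e*mV


def interp_pmf(h, grid_h, grid_u, cap=500.0):
    """Hand-rolled linear interpolation with wall extrapolation and tail zero."""
    if h >= grid_h[-1]:
        return 0.0
    if h < grid_h[0]:
        slope = (grid_u[1] - grid_u[0]) / (grid_h[1] - grid_h[0])
        return min(grid_u[0] + slope * (h - grid_h[0]), cap)
    for j in range(len(grid_h) - 1):
        if grid_h[j] <= h <= grid_h[j + 1]:
            t = (h - grid_h[j]) / (grid_h[j + 1] - grid_h[j])
            return grid_u[j] * (1 - t) + grid_u[j + 1] * t
    raise AssertionError("unreachable")


def hamaker_two_sphere(A, R1, R2, h):
    d2 = (R1 + R2 + h) ** 2
    sp = (R1 + R2) ** 2
    sm = (R1 - R2) ** 2
    return -(A / 6.0) * (2 * R1 * R2 / (d2 - sp) + 2 * R1 * R2 / (d2 - sm)
                         + math.log((d2 - sp) / (d2 - sm)))


def hamaker_sphere_wall(A, R2, h):
    """Closed-form sphere near an infinite flat wall."""
    return -(A / 6.0) * (R2 / h + R2 / (h + 2 * R2) + math.log(h / (h + 2 * R2)))


def bead_u(res, q, h, R, zeta, kappa, pmf, hamaker, r_cutoff, r_bead, spherical=True):
    geom = R / (R + h) if spherical else 1.0
    u = q * F_MV * zeta * geom * math.exp(-kappa * h)
    gh, gu = pmf[res]
    u += interp_pmf(h, gh, gu)
    if h >= r_cutoff:
        u += hamaker_two_sphere(hamaker[res], R, r_bead, h) \
            - hamaker_two_sphere(hamaker[res], R, r_bead, r_cutoff)
    return u


def protein_u(positions, residues, charges, z, R, zeta, kappa, pmf, hamaker,
              r_cutoff, r_bead=0.5):
    """Direct pairwise sum; +inf if any bead penetrates the particle."""
    total = 0.0
    for (x, y, pz), res, q in zip(positions, residues, charges):
        d = math.sqrt(x * x + y * y + (pz + z) ** 2)
        h = d - R
        if h < 0:
            return math.inf
        total += bead_u(res, q, h, R, zeta, kappa, pmf, hamaker, r_cutoff, r_bead)
    return total


def boltzmann_mean_direct(us, T):
    """Direct weighted sum (no shift) — valid for moderate energies."""
    kt = KB * T
    num = math.fsum(u * math.exp(-u / kt) for u in us if math.isfinite(u))
    den = math.fsum(math.exp(-u / kt) for u in us if math.isfinite(u))
    return num / den


def e_ads_direct(thetas, phis, E, T, delta, sin_weight=True):
    """Direct Boltzmann average over heatmap bins."""
    kt = KB * T
    terms_n, terms_d = [], []
    for k, th in enumerate(thetas):
        w_geo = math.sin(math.radians(th + delta / 2.0)) if sin_weight else 1.0
        for l in range(len(phis)):
            w = w_geo * math.exp(-E[k][l] / kt)
            terms_n.append(w * E[k][l])
            terms_d.append(w)
    return math.fsum(terms_n) / math.fsum(terms_d)


def rotate(positions, phi_deg, theta_deg):
    """Explicit R_y(180 - theta) @ R_z(-phi) applied to each position."""
    a = math.radians(-phi_deg)
    b = math.radians(180.0 - theta_deg)
    out = []
    for x, y, z in positions:
        x1 = math.cos(a) * x - math.sin(a) * y
        y1 = math.sin(a) * x + math.cos(a) * y
        z1 = z
        x2 = math.cos(b) * x1 + math.sin(b) * z1
        z2 = -math.sin(b) * x1 + math.cos(b) * z1
        out.append((x2, y1, z2))
    return out


def contact_z_bisect(positions, R, lo=None, hi=None, tol=1e-12):
    """Bisection solve of min_i h_i(z) = 0."""
    def min_h(z):
        return min(math.sqrt(x * x + y * y + (pz + z) ** 2) for x, y, pz in positions) - R

    span = max(math.sqrt(x * x + y * y + pz * pz) for x, y, pz in positions)
    if lo is None:
        lo = R - span - 1.0
    if hi is None:
        hi = R + span + 1.0
    assert min_h(lo) < 0 < min_h(hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if min_h(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return hi  # the non-penetrating end of the bracket


def brute_force_dock(positions, residues, charges, R, zeta, kappa, pmf, hamaker,
                     r_cutoff, T, delta=45.0, h_max=2.0, dz=0.05, sin_weight=True):
    """Full pipeline at bin-centre sampling, n_bin = 1: returns (E grid, E_ads)."""
    n_phi = int(360 / delta)
    n_theta = int(180 / delta)
    n_steps = int(math.ceil(h_max / dz))
    E = [[0.0] * n_phi for _ in range(n_theta)]
    for k in range(n_theta):
        for l in range(n_phi):
            rot = rotate(positions, l * delta + delta / 2, k * delta + delta / 2)
            z0 = contact_z_bisect(rot, R)
            us = [
                protein_u(rot, residues, charges, z0 + j * dz, R, zeta, kappa,
                          pmf, hamaker, r_cutoff)
                for j in range(n_steps + 1)
            ]
            E[k][l] = boltzmann_mean_direct(us, T)
    thetas = [k * delta for k in range(n_theta)]
    phis = [l * delta for l in range(n_phi)]
    return E, e_ads_direct(thetas, phis, E, T, delta, sin_weight)
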