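# nanodock

Coarse-grained rigid-body docking of proteins onto spherical
nanoparticles: orientation-energy heatmaps, Boltzmann-averaged adsorption
energies, and docked-pose structures.

When a protein meets a nanoparticle it physisorbs in some preferred
orientation, and that orientation decides whether functional sites (an
antibody's antigen-binding domains, an enzyme's active site) stay
accessible. Atomistic simulation of this is far too slow for screening,
so `nanodock` uses a multiscale shortcut: the protein becomes one bead per
residue at the Cα position, the particle a sphere of radius R with surface
potential ζ, and every residue–surface interaction is evaluated from
precomputed ingredients. It is a prescreening tool for people designing
nanoparticle–protein systems (immunoassays, biosensors, corona
prediction) who need energy rankings and orientation candidates, not
refined complexes.

## Model

The protein–particle energy at centre–centre geometry is pairwise
additive over beads. A bead of residue type *i* and fractional charge
*q_i* at surface separation *h_i = d_i − R* contributes

- **screened electrostatics** — Debye–Hückel potential outside a charged
  sphere: *U_el = q_i F ζ · R/(R+h_i) · exp(−κ h_i)*, with
  κ = λ_D⁻¹ = (8π l_B n)^{1/2} and Bjerrum length
  l_B = e²/(4π ε ε₀ k_B T);
- **a tabulated surface PMF** *U_s(h_i)* for that residue type on that
  material (and Miller plane *hkl*), active at short range;
- **a Hamaker two-sphere van der Waals term** *U_c(h_i)* toward the
  particle core, switched on beyond the PMF cutoff r_cutoff and offset to
  join continuously.

Fractional charges come from Henderson–Hasselbalch at the chosen pH
(model pKa values; externally computed charges, e.g. PropKa output, can
be loaded instead). For each orientation (φ, θ) — defined by rotating
the canonical principal-axis frame with R_y(180°−θ)·R_z(−φ) — the energy
is evaluated on a ladder of separations from closest-bead contact to
h_max = 2 nm and Boltzmann-averaged into one orientation energy
E(θ_k, φ_l). Bins of width δ (default 5°) are each sampled with N_bin
(default 6) random orientations, giving the heatmap mean and SD. The
global adsorption energy is the Boltzmann-weighted average over bins,

E_ads = Σ_kl P_kl E_kl,  P_kl ∝ sin(θ_k + δ/2) · exp(−E_kl / k_B T),

and every heatmap local minimum within one SD of the absolute minimum is
reported as a candidate docking pose.

## Worked example

`examples/03_dock_helix.py` docks a 20-residue helix on a 15 nm, −20 mV
synthetic-material particle at 15° resolution:

```
scanned 864 orientation samples (24 x 12 bins x 3)
E_ads (Boltzmann average over orientations): -57.62 kJ/mol
deepest bin: -60.10 +/- 15.56 kJ/mol at (phi=105, theta=75)
candidate poses within 1 SD of the minimum (E <= -44.54 kJ/mol): 7
```

Negative E_ads means adsorption is favourable; the deepest bin is the
single best orientation, and the seven candidates are all heatmap minima
close enough to it (within its sampling SD) that the rigid-body model
cannot rank them reliably — they are the poses worth refining. The other
examples show structure preparation and charging, material generation and
I/O, and pure electrostatic orientation steering of a charge-dipole rod.

The same pipeline is available as a CLI:

```
nanodock dock --pdb protein.pdb --radius-nm 15 --zeta-mv -20 --ph 7.3
nanodock pose --pdb protein.pdb --phi 180 --theta 30
```

`dock` writes the UAM table (per-bin energy, SD, minimum surface
distance), the heatmap PNG, `material.dat` and a CONFIG file; `pose`
writes the docked structure as CA-only PDB and XYZ. Real material
parameter sets (one PMF file per residue under `<material>/<hkl>/`) are
used via `--materials-dir`; the built-in `TESTMAT` is synthetic.

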