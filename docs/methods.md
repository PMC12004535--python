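# Methods

## Coarse-grained representation and frames

A protein is reduced to one bead per residue at the Cα coordinate (Å in
the PDB file, stored in nm). Only ATOM records of standard amino acids
are kept; common modified residues (MSE, SEC, …) are mapped to their
parent type, everything else — waters, ligands, HETATM — is dropped. For
alternate locations the first-listed conformer wins; residue identity is
(chain, resSeq, iCode); only the first MODEL of an ensemble is read.
Residues without a Cα are dropped with a warning rather than raising,
because chain breaks are routine in deposited structures.

Canonicalization translates the bead centroid to the origin and rotates
the cloud so the principal axis of **largest spatial extent** lies on z
and the second-largest on y, using unit bead masses (the centroid is
geometric; a mass-weighted variant was considered and rejected as an
unnecessary extra parameter — bead masses vary by ~2× while positions
vary by the whole protein diameter). Axis signs are fixed by requiring
the bead farthest from the origin to have non-negative z, then
non-negative y, and the x axis is y×z so the rotation is proper. Note
the convention is stated here operationally because "highest moment of
inertia" phrasing is ambiguous: the long axis has the *smallest* moment
about itself. We align largest extent → z.

An orientation (φ ∈ [0°,360°), θ ∈ [0°,180°]) denotes the canonical-frame
unit vector with azimuth φ and polar angle θ that is turned to face the
particle; the realising rotation is R_y(180°−θ)·R_z(−φ), so (φ,θ) =
(0°,180°) is the identity.

## Protonation

Side-chain charges are Henderson–Hasselbalch populations:
acid −1/(1+10^(pKa−pH)), base +1/(1+10^(pH−pKa)), with model pKa values
ASP 3.65, GLU 4.25, HIS 6.0, CYS 8.3, TYR 10.07, LYS 10.53, ARG 12.48,
N-terminus 8.0, C-terminus 3.6. Terminal charges fold into the first and
last bead of each chain. Fractional rather than rounded charges are used
because the electrostatic energy is linear in q, so the population
average of the energy equals the energy of the average charge. This is a
sequence-level model: structural pKa shifts (burial, salt bridges) are
deliberately out of scope, and `load_external_charges` accepts per-residue
charges computed by a structure-aware tool instead.

## Materials

A material supplies, per residue type, a Hamaker constant A_i (kJ/mol)
and a tabulated PMF u(h) on a strictly increasing surface-separation grid
(nm) that must have decayed to |u| ≤ 0.5 kJ/mol at its last node. PMF
lookup is linear interpolation; beyond the last node the potential is 0;
below the first node it is linearly extrapolated from the first two nodes
and capped at +500 kJ/mol — a hard wall far above any thermally
accessible energy that keeps Boltzmann weights finite as h → 0. The disk
layout is one two-column text file per residue under
`<material>/<hkl>/<AA3>.dat` plus `material.dat` with the Hamaker lines;
`hkl` is "000" for amorphous materials. Default r_cutoff = 1.0 nm,
overridable per material.

The synthetic generator tabulates a 9-3 wall,
u(h) = ε_r[(2/15)(σ/(h+σ))⁹ − (σ/(h+σ))³], shifted to exactly 0 at the
cutoff, with per-residue depths ε_r of 5–20 kJ/mol (aromatic and
sulfur-bearing residues deepest, matching the generic trend on inorganic
surfaces) and σ = 0.35 nm. Note that with s = σ/(h+σ) ≤ 1 this form is
monotonically attractive down to contact — its minimum sits at h = 0 —
which is acceptable for a test material because the separation window
starts at contact anyway. It emulates the *shape and scale* of
MD-derived residue–surface PMFs, not any real material: passing tests
demonstrate the machinery (interpolation, splicing, averaging), not
chemical accuracy for silver or silica.

## Energy model

Distances: h_i = d_i − R is surface-to-bead-centre; the bead's own radius
(default 0.5 nm, a typical side-chain scale) enters only the Hamaker
term, whose centre separation is R + r_bead + h.

Electrostatics uses the linearized-PB solution outside a sphere,
q F ζ (R/(R+h)) e^(−κh), which reduces to the flat exponential form as
R → ∞; a flag selects strict flat mode. F = 0.0964853 kJ·mol⁻¹ per e·mV.
κ comes from a 1:1 electrolyte at the stated molar ionic strength.

The Hamaker core term is the classic two-sphere closed form. It is
multiplied by a step switch (0 below r_cutoff, 1 at and above) and offset
by −U_c(r_cutoff) so the total is continuous at the splice; the PMF is
trusted exclusively at short range because it already contains
dispersion. Consequence of the constant offset: beyond the cutoff the
total tends to +|U_c(r_cutoff)| rather than 0 at infinite separation.
Within the 2 nm separation window this constant is small (≲1 kJ/mol for
the synthetic material) and identical across orientations, so heatmap
*differences* are unaffected; it is the documented cost of a
C⁰-continuous splice with a step switch.

Any bead with h < 0 (inside the particle) marks the configuration as a
hard overlap: the total is +inf and the configuration gets zero Boltzmann
weight. A tolerance of 1e−9 nm guards the exact-contact start point of
the ladder against floating-point noise.

## Scan and statistics

Per orientation, the separation ladder starts at closest-bead contact
(z₀ solved in closed form per bead, cross-checked against bisection in
the tests) and climbs in dz = 0.05 nm steps to h_max = 2.0 nm (41
energies) — a resolution/cost compromise: halving dz changed ladder
means by ≲0.1 kJ/mol on the synthetic material. The orientation energy
is the Boltzmann mean over the ladder (min-shifted exponentials for
stability). A free-energy variant, −k_B T ln⟨e^(−U/kT)⟩, is available
behind a flag; the mean-energy form is the default reducer.

Bins of width δ (default 5°, giving 72×36 bins) are sampled with n_bin
(default 6) orientations drawn uniformly in (φ, θ) within the bin from a
seeded generator — bins are small, and the sphere-area correction is
applied once at the E_ads stage rather than per draw. The bin energy is
the arithmetic mean of the n_bin ladder means and the bin SD its sample
standard deviation (ddof = 1; defined as 0 when n_bin = 1), so the SD
written to the UAM file is the dispersion of exactly the quantity
averaged. The per-bin minimum surface distance is the closest-approach
separation at which any sample's ladder attains its energy minimum. A
configuration cap (360/δ)(180/δ)·n_bin < 16200 is enforced before any
computation. Bin-centre sampling (`sample_mode="center"`) exists for
deterministic comparisons against brute-force reimplementation.

E_ads weights each bin by sin(θ_k + δ/2)·exp(−E_kl/k_B T), normalised:
the sine factor is the spherical area element needed for
uniform-over-orientations weighting on a regular (φ, θ) grid; a switch
disables it for strict grid averaging.

Candidate poses are 8-neighbourhood local minima on the grid (periodic
in φ, clamped at the θ edges — θ = 0 and 180 are poles, not wrap-around)
with E ≤ E_min + SD(E_min), sorted by energy, ties broken by (θ, φ).
The one-SD rule reflects the sampling uncertainty of each bin: minima
closer than one SD are not distinguishable by this model, and strong
adsorption makes equilibration between minima slow in reality, so all of
them deserve consideration. The pose for a chosen orientation sits at the
ladder's energy minimum z*; a purely repulsive ladder puts z* at the
window edge and is flagged.

## Defaults and problem sizes

T = 309.75 K, I = 0.15 M and pH ≈ 7 defaults correspond to physiological
conditions; ε_r = 78.4. Unit tests run at coarse resolution (δ = 45° or
15°, n_bin ≤ 3) on 3–20-bead fixtures, which exercises every code path
identically to fine grids; the acceptance script runs the full default
resolution (15 552 profile evaluations) on a 20-residue helix, a size at
which a complete default-resolution scan takes seconds while displaying
every statistic the tool reports.

## Limitations

Rigid protein and rigid sphere: no flexibility, unfolding, or entropic
terms beyond the separation/orientation averaging; binding energies of
flexible proteins are underestimated and some poses may be missed. One
protein, one particle: no corona crowding, no multi-bead or coated
particles. PMFs are consumed as flat-slab tables with no curvature
correction for small radii. The synthetic material is a stand-in for
testing; quantitative predictions require measured parameter sets. The
heatmap minimum is a low-resolution model: candidates should be refined
by higher-resolution simulation before being treated as structures.
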