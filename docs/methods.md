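# Methods

`cgmemsim` implements a coarse-grained (CG) model for transmembrane
protein–lipid systems together with the MD machinery and analyses needed
to study hydrophobic mismatch with WALP model peptides.

## The model

**Mapping.** Each amino acid maps to two spherical interaction sites: a
backbone bead at the Cα position (types `BB`, `BP` for Pro, `BG` for
Gly, differing only in mass; Gly carries no sidechain bead) and a
sidechain bead on the Cα→Cβ ray at a residue-specific distance.  Lipids
are head/tail bead chains from a companion bilayer model: `H4T3T3`
(DLPC-like, 4 head beads, two 3-bead tails) and `H4T4T4` (DPPC-like,
two 4-bead tails).  Water is a single bead species `W`.

**Potential.** The total energy is

V = Σ V_LJ(r_ij) + Σ′ V_LJHB(r_ij) + Σ ½k(r−r₀)² + Σ ½k_θ(θ−θ₀)²
    + Σ V_A(θ_ijk)

with plain 12-6 Lennard-Jones pairs (purely repulsive pairs use the
Weeks–Chandler–Andersen truncation), harmonic bonds, harmonic lipid-tail
angles (θ₀ = 180°, k = 5.408 kJ/mol/rad²), and two model-specific
terms:

* **Double angle potential** `V_A(θ) = A·g(θ) + D`, where `g` is a
  quartic whose derivative is `(θ−θ₁)(θ−θ₂)(θ−ξ)`.  Five parameters
  define it — the two equilibrium angles, their well energies and the
  barrier energy — and the barrier *position* ξ is solved at
  construction by Newton–Raphson (midpoint start, bisection fallback)
  on the residual V(θ₂; ξ) − V(θ₂).  Backbone triples use wells at
  91.25° (0 kJ/mol, the helix basin) and 123.25° (23.0 kJ/mol, the
  coil basin) with a 23.7 kJ/mol barrier.  Backbone–backbone–sidechain
  triples use wells at 118°/135° (both 0) and a 0.003 kJ/mol barrier,
  which keeps the sidechain on the outward bisector of the local
  backbone bend without hindering its motion.
* **LJHB potential** `V_LJ(r) − η·exp(−(r−μ)²/2κ²)` between backbone
  beads only (and only for pairs separated by three or more bonds):
  an inverted Gaussian hydrogen-bond well at μ = 0.61 nm (width
  κ = 0.015 nm, depth η = 15.0 kJ/mol) that stabilises the i,i+4
  α-helical register without torsion terms or per-residue secondary-
  structure typing.

**Nonbonded rules.** σ_ij follows the contact rule 2^(1/6)σ_ij = R_i +
R_j (LJ minimum at the contact of the two van der Waals spheres); the
backbone radius is set so the BB–BB minimum falls at 0.448 nm.  Pairs
directly bonded or joined through an angle are excluded.  Cutoff 1.2 nm
with an energy shift to zero at the cutoff (WCA needs no shift).
Interaction strengths are organised by group — polar sidechains and all
backbone beads, apolar, aromatic, neutral, lipid head, lipid tail,
water — with the environment tiers: polar↔water 1.97, polar↔head 0.50
(Gly backbone 1.00), polar↔tail WCA; apolar↔tail 1.97 (Met 1.00),
apolar↔head 0.50 (Phe 1.00), apolar↔water WCA; aromatic↔head 1.97,
otherwise WCA; neutral↔anything 0.50 (all kJ/mol).

**Parameter provenance.** Bead masses are computed from residue
composition (sidechain = residue − 56.04 amu backbone unit).  Radii are
reconstructed from occupied residue volumes (sidechain volume = residue
minus glycine; Arg set equal to Phe, which has the same heavy-atom
count), uniformly rescaled to anchor the 0.448 nm backbone contact.
Sidechain bond lengths are averaged-PDB-geometry estimates.  Bond force
constants (5000 kJ/mol/nm², disulfide 2500), the lipid/water bead
parameters (H/T/W masses 60/56/54 amu, radii 0.24–0.26 nm) and the
protein–protein and environment–environment ε matrix are this package's
own estimates, chosen for a liquid water phase and a stable fluid
bilayer at 324 K and stability at the 12 fs step; they are flagged as
estimates in `data/forcefield.toml` and can be replaced wholesale by
editing that file.

## Simulation engine

Leapfrog integration at dt = 12 fs; Berendsen thermostat
(τ_T = 0.1 ps) and Berendsen barostat (τ_P = 1.0 ps, compressibility
4.5×10⁻⁵ atm⁻¹), semi-isotropic for membranes (x,y coupled, z free) and
isotropic for solution; box-scaling factors are clipped to ±2% per step
so an unequilibrated start cannot collapse the box.  Velocities are
Maxwell–Boltzmann at the target temperature from a recorded seed, with
centre-of-mass motion removed; trajectories are bit-reproducible for a
fixed seed.  Freshly assembled systems should be relaxed with
`minimize_energy` (adaptive steepest descent, displacements capped at
0.02 nm/step) before dynamics: the lattice-contact strain of an
unrelaxed start otherwise appears as a several-hundred-kelvin
temperature transient that can topple an embedded peptide or buckle a
small bilayer patch.  Nonbonded interactions run over an all-pairs Verlet
neighbor list (skin 0.3 nm, rebuilt when any particle moves half a
skin), with minimum-image periodic boundaries; kernels are numba-
compiled.  Instantaneous kinetic energy is reported from half-step-
synchronised velocities so NVE conservation is measurable.  Steered
pulls attach selected beads by a harmonic spring (default
100 kJ/mol/nm²) to a phantom particle moving at constant velocity
(default 0.002 nm/ps, two orders of magnitude below thermal speeds) and
record the probe depth relative to the instantaneous lipid midplane and
the probe–environment nonbonded energy.

## System builders

* **Peptides** — ideal α-helix Cα geometry: 0.15 nm rise, 100° twist,
  0.23 nm helix radius.  These constants reproduce both the 0.384 nm
  consecutive-bead bond and the 0.61 nm i,i+4 H-bond distance that the
  force field targets.  Sidechains point radially outward.  `walp_sequence(n)`
  generates Gly + Trp–Trp + alternating Leu/Ala core + Trp–Trp + Ala
  (WALP16 = GWWLALALALALAWWA).
* **Mapping** — backbone bead at Cα, sidechain on the Cα→Cβ ray; chains
  and numbering gaps split bonded segments (missing residues are never
  modeled); disulfides bridge flagged cysteine pairs; a missing Cβ on a
  non-Gly residue falls back to the outward backbone bisector (with a
  warning) or errors, per caller's choice.
* **Membranes** — two leaflets on a square lattice at 0.65 nm²/lipid
  (configurable), tails pointing to the midplane with a 0.4 nm tip gap,
  alternate rows offset by a quarter spacing for packing.  The
  stiffened-tail flag doubles the tail angle constant
  (5.408 → 10.816 kJ/mol/rad²), the rigid-membrane control.
* **Solvation** — the peptide is centred on the bilayer midplane with
  its axis along +z; lipids with any bead within 0.9× contact distance
  of a peptide bead are removed whole; water fills the rest on a
  0.45 nm lattice under the same overlap rule.

## Analyses

* CRMSα: backbone-bead RMS deviation after optimal superposition
  (Kabsch, via scipy); superposition is on by default because whole-body
  diffusion would otherwise dominate, and can be disabled.
* Radius of gyration: unweighted RMS distance to the geometric centre
  (deliberately not mass-weighted).
* H-bond registers: normalised histograms of backbone i,i+3 / i,i+4 /
  i,i+5 distances with a mode locator (0.005 nm bins).
* Membrane thickness: the xy box is tiled into a 17×17 grid (fewer
  sections are advisable for small patches); each lipid contributes its
  head-adjacent first tail beads; a section's thickness is the mean of
  2·|z − z_mid| over its beads with z_mid the per-section mean.
* Mismatch report: dP = distance between the centroids of the four
  N-terminal and four C-terminal backbone beads; the helix axis joins
  the same centroids; tilt is measured against +z and folded into
  [0°, 90°]; dL = far-field grid thickness; adaptation = near − far
  (near: sections within 1.5 nm of the peptide axis; far: beyond
  3.0 nm, clamped to the half-box in small patches).  All quantities
  are averaged over a trailing window, 240 ps by default.

## Problem sizes used by the test suite

The shipped tests run the physics end-to-end at desk scale: helix
self-maintenance uses WALP23 in vacuum for 1.5 ns; the membrane sweeps
use a ~4×4 nm patch (≈50 lipids, ≈800 beads with water), energy-
minimised, then 1.2 ns of NPT dynamics per peptide, one replicate,
analysed over the final 240 ps with a 5×5 thickness grid.  At this
scale the structural-stability results, the thinning of the bilayer
around a negatively mismatched peptide and the monotone rise of
adaptation with mismatch are reproduced.  Two full-scale results are
not: the ≈0.15 nm adaptation plateau (the 1.5 nm near field covers
nearly the whole small patch, diluting the local signal) and the large
(≈70°) tilt of strongly mismatched helices (tilt is a slow collective
mode, far from equilibrated within ~1 ns, and a long helix in a ~4 nm
periodic box meets its own image when rotating toward the plane).  The
corresponding checks keep the full-scale expectations and document the
desk-scale values they measure.  Full-scale studies (10×10 nm, tens of
ns, several replicates) use the same code paths unchanged; only
wall-clock time separates them.

## Known limitations

* No electrostatics, torsions or constraints (by model design).
* The hydrogen-bond well is isotropic; directional H-bonding is a known
  model refinement left out here.
* Tables of per-residue radii, sidechain bond lengths and the
  protein–protein ε matrix are reconstructions (see provenance above);
  absolute partitioning free energies should not be over-interpreted.
* Berendsen coupling does not sample a rigorous NPT ensemble;
  fluctuation-based observables (compressibility, heat capacity) are
  out of scope.
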