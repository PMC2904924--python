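# cgmemsim

Coarse-grained molecular dynamics of transmembrane protein–lipid
systems: two beads per residue, a double-well backbone angle potential,
and a Gaussian-augmented Lennard-Jones hydrogen-bond potential.

## The problem

Membrane proteins live or die by how well the hydrophobic span of their
transmembrane helices matches the hydrophobic thickness of the bilayer.
Studying that *hydrophobic mismatch* — and the two mechanisms that
relieve it, local membrane thickening and helix tilting — needs
simulations of tens of nanoseconds over thousands of lipids, beyond
routine all-atom budgets.  `cgmemsim` implements a coarse-grained model
built for exactly this regime and aimed at α-helical membrane proteins
and their standard experimental proxies, the WALP peptides
(Trp-flanked Leu/Ala helices, e.g. WALP16 = `GWWLALALALALAWWA`).

## The model in brief

Each residue maps to a backbone bead at Cα plus one sidechain bead on
the Cα→Cβ ray; lipids are head/tail bead chains (`H4T3T3` ≈ DLPC,
`H4T4T4` ≈ DPPC); water is a single bead.  The potential is

```
V = Σ V_LJ + Σ' V_LJHB + Σ ½k(r−r₀)² + Σ ½k_θ(θ−θ₀)² + Σ V_A(θ)
```

with two model-specific terms that replace torsions and secondary-
structure typing:

* the **double angle potential** `V_A(θ) = A·g(θ) + D`, a quartic with
  minima at the helix (91.25°, 0 kJ/mol) and coil (123.25°,
  23.0 kJ/mol) backbone angles separated by a 23.7 kJ/mol barrier at an
  angle ξ solved by Newton–Raphson at construction;
* the **LJHB potential** `V_LJ(r) − η·e^{−(r−μ)²/2κ²}`, a Lennard-Jones
  term plus an inverted Gaussian well at the backbone–backbone
  hydrogen-bond distance (μ = 0.61 nm, η = 15 kJ/mol), active between
  backbone beads more than two bonds apart.

The engine integrates with leapfrog at 12 fs under Berendsen
temperature/pressure coupling and supports steered pulls via a
phantom-particle spring.  See `docs/methods.md` for the full model,
parameter provenance and limitations.

## Worked example

`examples/membrane_mismatch.py` embeds a WALP23 helix in a small
DLPC-like bilayer patch, energy-minimises, runs 0.5 ns of NPT dynamics
and measures the mismatch observables:

```
WALP23 in H4T3T3: 1152 beads, box [4.84 4.84 6.1 ] nm
simulated 480 ps at 293 K / 1 atm
  dP (peptide hydrophobic length) : 2.65 nm
  dL (far-field bilayer thickness): 1.54 nm
  hydrophobic mismatch dP - dL    : +1.11 nm
  membrane adaptation (near - far): -0.056 nm
  helix tilt vs membrane normal   : 12.7 deg
  peptide CRMS vs start           : 0.213 nm
```

dP is the distance between the centroids of the four N- and C-terminal
backbone beads, dL the bilayer hydrophobic thickness far from the
peptide (17×17-style grid of first-tail beads, here 5×5 for the small
patch).  The helix stays transmembrane with its fold intact (CRMSα
well below the 0.384 nm backbone bond, the model's characteristic
length); relieving a positive mismatch of this size by thickening or
tilting develops over tens of nanoseconds at full scale.  The other examples cover the
double-well angle term (`double_well_angle.py`), helix
self-maintenance in vacuum (`helix_stability.py`), CG mapping of
structures (`map_structure.py`, also accepts a PDB file) and the
steered-pull partitioning protocol (`steered_pull.py`).

A thin CLI wraps the same library:

```sh
cgmemsim build-walp --sequence GWWLALALALALAWWA --out walp16
cgmemsim run --system walp16 --n-steps 50000 --seed 7 --out traj
cgmemsim analyze crms --system walp16 --traj traj.xyz
```

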