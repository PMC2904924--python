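# Default coarse-grained force field for transmembrane protein/lipid systems.
#
# Units: mass amu, lengths nm, energies kJ/mol, angles degrees,
# bond constants kJ/mol/nm^2, angle constants kJ/mol/rad^2.
#
# Provenance of the numbers:
#   * backbone bond length (0.384 nm), the double-angle parameter sets,
#     the LJHB hydrogen-bond well (mu 0.61 nm, kappa 0.015 nm, eta
#     15.0 kJ/mol), the lipid tail angle (180 deg, 5.408 kJ/mol/rad^2)
#     and the protein-environment energy tiers (1.97 / 1.00 / 0.50
#     kJ/mol, repulsive-only pairs as WCA) are the published model
#     constants;
#   * bead masses are computed from residue chemical composition
#     (sidechain mass = residue mass minus the 56.04 amu backbone unit);
#   * bead radii are ESTIMATES reconstructed from occupied residue
#     volumes (sidechain volume = residue volume minus glycine; Arg set
#     equal to Phe), uniformly rescaled so that the backbone-backbone
#     Lennard-Jones minimum falls at the published 0.448 nm;
#   * sidechain bond lengths are ESTIMATES of C-alpha to sidechain
#     centroid distances from averaged PDB geometry;
#   * bond force constants, lipid/water bead parameters and the
#     protein-protein / environment-environment energy matrix are
#     ESTIMATES chosen for numerical stability at a 12 fs time step and
#     for a liquid water phase and stable fluid bilayer at 324 K.

[types]
BB = { mass = 56.04, radius = 0.224, group = "polar" }
BP = { mass = 55.04, radius = 0.224, group = "polar" }
BG = { mass = 57.05, radius = 0.224, group = "polar" }
SA = { mass = 15.04, radius = 0.1620, group = "apolar" }
SC = { mass = 47.10, radius = 0.1879, group = "neutral" }
SD = { mass = 59.05, radius = 0.2142, group = "polar" }
SE = { mass = 73.08, radius = 0.2467, group = "polar" }
SF = { mass = 91.14, radius = 0.2852, group = "apolar" }
SH = { mass = 81.10, radius = 0.2575, group = "aromatic" }
SI = { mass = 57.12, radius = 0.2588, group = "apolar" }
SK = { mass = 72.13, radius = 0.2609, group = "polar" }
SL = { mass = 57.12, radius = 0.2580, group = "apolar" }
SM = { mass = 75.15, radius = 0.2605, group = "apolar" }
SN = { mass = 58.06, radius = 0.2267, group = "polar" }
SP = { mass = 42.08, radius = 0.2200, group = "polar" }
SQ = { mass = 72.09, radius = 0.2521, group = "polar" }
SR = { mass = 100.15, radius = 0.2852, group = "polar" }
SS = { mass = 31.04, radius = 0.1769, group = "neutral" }
ST = { mass = 45.06, radius = 0.2113, group = "neutral" }
SV = { mass = 43.09, radius = 0.2336, group = "apolar" }
SW = { mass = 130.17, radius = 0.3072, group = "aromatic" }
SY = { mass = 107.14, radius = 0.2853, group = "aromatic" }
H = { mass = 60.0, radius = 0.26, group = "lipid-head" }
T = { mass = 56.0, radius = 0.26, group = "lipid-tail" }
W = { mass = 54.0, radius = 0.24, group = "water" }

[bonds]
"BB-BB" = { r0 = 0.384, k = 5000.0 }
"BB-BP" = { r0 = 0.384, k = 5000.0 }
"BB-BG" = { r0 = 0.384, k = 5000.0 }
"BP-BP" = { r0 = 0.384, k = 5000.0 }
"BP-BG" = { r0 = 0.384, k = 5000.0 }
"BG-BG" = { r0 = 0.384, k = 5000.0 }
"BB-SA" = { r0 = 0.153, k = 5000.0 }
"BB-SC" = { r0 = 0.181, k = 5000.0 }
"BB-SD" = { r0 = 0.220, k = 5000.0 }
"BB-SE" = { r0 = 0.270, k = 5000.0 }
"BB-SF" = { r0 = 0.256, k = 5000.0 }
"BB-SH" = { r0 = 0.240, k = 5000.0 }
"BB-SI" = { r0 = 0.205, k = 5000.0 }
"BB-SK" = { r0 = 0.300, k = 5000.0 }
"BB-SL" = { r0 = 0.226, k = 5000.0 }
"BB-SM" = { r0 = 0.270, k = 5000.0 }
"BB-SN" = { r0 = 0.222, k = 5000.0 }
"BP-SP" = { r0 = 0.150, k = 5000.0 }
"BB-SQ" = { r0 = 0.272, k = 5000.0 }
"BB-SR" = { r0 = 0.350, k = 5000.0 }
"BB-SS" = { r0 = 0.170, k = 5000.0 }
"BB-ST" = { r0 = 0.168, k = 5000.0 }
"BB-SV" = { r0 = 0.166, k = 5000.0 }
"BB-SW" = { r0 = 0.290, k = 5000.0 }
"BB-SY" = { r0 = 0.300, k = 5000.0 }
# disulfide bridge between flagged cysteine sidechain beads
"SC-SC" = { r0 = 0.550, k = 2500.0 }
"H-H" = { r0 = 0.33, k = 5000.0 }
"H-T" = { r0 = 0.33, k = 5000.0 }
"T-T" = { r0 = 0.33, k = 5000.0 }

[angles.harmonic]
# lipid tail rigidity; the stiffened-tail control doubles k to 10.82
lipid-tail = { theta0 = 180.0, k = 5.408 }

[angles.double]
# backbone triple: helix well at 91.25 deg (0 kJ/mol), coil well at
# 123.25 deg (23.0 kJ/mol), barrier 23.7 kJ/mol
backbone = { theta1 = 91.25, theta2 = 123.25, V1 = 0.0, V2 = 23.0, Vbar = 23.7 }
# backbone-backbone-sidechain triple: outward-bisector wells, tiny barrier
backbone-sidechain = { theta1 = 118.0, theta2 = 135.0, V1 = 0.0, V2 = 0.0, Vbar = 0.003 }

[pairs.groups]
# unordered interaction-group matrix; numbers are LJ well depths
# (kJ/mol), "wca" marks repulsive-only pairs
"polar:polar" = 1.97
"polar:apolar" = "wca"
"polar:aromatic" = 0.50
"polar:neutral" = 0.50
"polar:lipid-head" = 0.50
"polar:lipid-tail" = "wca"
"polar:water" = 1.97
"apolar:apolar" = 1.97
"apolar:aromatic" = 1.00
"apolar:neutral" = 0.50
"apolar:lipid-head" = 0.50
"apolar:lipid-tail" = 1.97
"apolar:water" = "wca"
"aromatic:aromatic" = 1.97
"aromatic:neutral" = 0.50
"aromatic:lipid-head" = 1.97
"aromatic:lipid-tail" = "wca"
"aromatic:water" = "wca"
"neutral:neutral" = 0.50
"neutral:lipid-head" = 0.50
"neutral:lipid-tail" = 0.50
"neutral:water" = 0.50
"lipid-head:lipid-head" = 2.0
"lipid-head:lipid-tail" = "wca"
"lipid-head:water" = 3.0
"lipid-tail:lipid-tail" = 2.5
"lipid-tail:water" = "wca"
"water:water" = 3.0

[pairs.types]
# per-type exceptions to the group matrix
"BG:H" = 1.00  # glycine backbone with lipid heads
"SM:T" = 1.00  # methionine with lipid tails
"SF:H" = 1.00  # phenylalanine with lipid heads

[pairs.ljhb]
# hydrogen-bond well appended to backbone-backbone Lennard-Jones pairs
mu = 0.61
kappa = 0.015
eta = 15.0
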