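"""System builders: CG mapping, ideal WALP helices, bilayers, solvation.

All builders return :class:`CGSystem` objects that carry particles,
bonded terms and the periodic box.  Coordinates are right-handed with
the membrane normal along +z and the bilayer midplane at z = 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .forcefield import (
    BondParams,
    DoubleAngleParams,
    ForceField,
    HarmonicAngleParams,
)

__all__ = [
    "CGSystem",
    "PeptideSpec",
    "BuildError",
    "map_structure_to_cg",
    "build_walp",
    "build_membrane",
    "solvate_and_embed",
    "walp_sequence",
    "ideal_helix_backbone",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# ideal alpha-helix C-alpha geometry used by the peptide generator
HELIX_RISE = 0.15  # nm per residue
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 0.23  # nm


class BuildError(ValueError):
    """Raised when a system cannot be constructed as requested."""


@dataclass
class PeptideSpec:
    """Sequence plus placement for a generated alpha-helical peptide."""

    sequence: str
    center: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: Tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        bad = set(self.sequence) - set("ACDEFGHIKLMNPQRSTVWY")
        if bad:
            raise BuildError(f"non-standard residue letters: {sorted(bad)}")


@dataclass
class CGSystem:
    """Particles, bonded topology and box of a coarse-grained system."""

    type_names: List[str] = field(default_factory=list)
    positions: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    molecule_ids: List[int] = field(default_factory=list)
    residue_indices: List[int] = field(default_factory=list)
    roles: List[str] = field(default_factory=list)
    bonds: List[Tuple[int, int, BondParams]] = field(default_factory=list)
    harmonic_angles: List[Tuple[int, int, int, HarmonicAngleParams]] = field(
        default_factory=list)
    double_angles: List[Tuple[int, int, int, DoubleAngleParams]] = field(
        default_factory=list)
    box: np.ndarray = field(default_factory=lambda: np.full(3, 50.0))
    periodic: Tuple[bool, bool, bool] = (False, False, False)
    velocities: Optional[np.ndarray] = None

    @property
    def n_particles(self) -> int:
        return len(self.type_names)

    def backbone_indices(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == "backbone"],
                        dtype=np.int64)

    def indices_with_role(self, role: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == role],
                        dtype=np.int64)

    def exclusion_pairs(self) -> Set[Tuple[int, int]]:
        """Nonbonded exclusions: bonded pairs and pairs joined through an angle."""
        excl: Set[Tuple[int, int]] = set()
        for i, j, _ in self.bonds:
            excl.add((min(i, j), max(i, j)))
        for i, j, k, _ in list(self.harmonic_angles) + list(self.double_angles):
            for a, b in ((i, j), (j, k), (i, k)):
                excl.add((min(a, b), max(a, b)))
        return excl

    def merge(self, other: "CGSystem") -> "CGSystem":
        """Concatenate two systems (molecule ids of ``other`` are shifted)."""
        off = self.n_particles
        mol_off = max(self.molecule_ids, default=-1) + 1
        out = CGSystem(
            type_names=self.type_names + other.type_names,
            positions=np.vstack([self.positions, other.positions]),
            molecule_ids=self.molecule_ids + [m + mol_off for m in other.molecule_ids],
            residue_indices=self.residue_indices + other.residue_indices,
            roles=self.roles + other.roles,
            bonds=self.bonds + [(i + off, j + off, p) for i, j, p in other.bonds],
            harmonic_angles=self.harmonic_angles + [
                (i + off, j + off, k + off, p) for i, j, k, p in other.harmonic_angles],
            double_angles=self.double_angles + [
                (i + off, j + off, k + off, p) for i, j, k, p in other.double_angles],
            box=self.box.copy(),
            periodic=self.periodic,
        )
        return out

    def validate(self, ff: ForceField) -> None:
        n = self.n_particles
        for t in self.type_names:
            if t not in ff.particle_types:
                raise BuildError(f"unknown particle type {t}")
        if self.positions.shape != (n, 3):
            raise BuildError("positions shape mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise BuildError("non-finite coordinates")
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise BuildError(f"bad bond ({i},{j})")
            if self.molecule_ids[i] != self.molecule_ids[j]:
                raise BuildError(f"bond ({i},{j}) crosses molecules")
        for i, j, k, _ in list(self.harmonic_angles) + list(self.double_angles):
            if len({i, j, k}) != 3 or not all(0 <= x < n for x in (i, j, k)):
                raise BuildError(f"bad angle ({i},{j},{k})")

    def masses(self, ff: ForceField) -> np.ndarray:
        return np.array([ff.particle_types[t].mass for t in self.type_names])


# ---------------------------------------------------------------------------
# peptides


def walp_sequence(n: int) -> str:
    """WALPn sequence: Gly + Trp pair + alternating Leu/Ala core + Trp pair + Ala."""
    if n < 8:
        raise BuildError("WALP peptides need at least 8 residues")
    core_len = n - 6
    core = ("LA" * ((core_len + 1) // 2))[:core_len]
    return "G" + "WW" + core + "WW" + "A"


def ideal_helix_backbone(n: int) -> np.ndarray:
    """C-alpha positions of an ideal alpha-helix along +z, centred at origin."""
    t = np.arange(n)
    phi = np.deg2rad(HELIX_TWIST) * t
    xyz = np.column_stack([
        HELIX_RADIUS * np.cos(phi),
        HELIX_RADIUS * np.sin(phi),
        HELIX_RISE * t,
    ])
    xyz[:, 2] -= xyz[:, 2].mean()
    return xyz


def _protein_topology(system: CGSystem, ff: ForceField,
                      chains: Sequence[Sequence[Tuple[int, Optional[int]]]]) -> None:
    """Add bonds and angles for chains of (backbone_idx, sidechain_idx) pairs."""
    bb_params = ff.double_angles["backbone"]
    bbs_params = ff.double_angles["backbone-sidechain"]
    for chain in chains:
        for r in range(len(chain)):
            b, s = chain[r]
            if s is not None:
                system.bonds.append((b, s, ff.bond_params(
                    system.type_names[b], system.type_names[s])))
            if r + 1 < len(chain):
                b2 = chain[r + 1][0]
                system.bonds.append((b, b2, ff.bond_params(
                    system.type_names[b], system.type_names[b2])))
        for r in range(1, len(chain) - 1):
            system.double_angles.append(
                (chain[r - 1][0], chain[r][0], chain[r + 1][0], bb_params))
        for r in range(len(chain)):
            b, s = chain[r]
            if s is None:
                continue
            for rr in (r - 1, r + 1):
                if 0 <= rr < len(chain):
                    system.double_angles.append((chain[rr][0], b, s, bbs_params))


def build_walp(spec: PeptideSpec, ff: ForceField) -> CGSystem:
    """CG peptide on ideal alpha-helix geometry, sidechains pointing outward.

    Backbone beads sit on a helix with 0.15 nm rise and 100 degrees of
    twist per residue at 0.23 nm radius, which reproduces the 0.384 nm
    consecutive-bead distance and the 0.61 nm i,i+4 hydrogen-bond
    distance the force field is built around.
    """
    seq = spec.sequence
    if len(seq) < 4:
        raise BuildError("peptide too short (need >= 4 residues)")
    bb = ideal_helix_backbone(len(seq))

    system = CGSystem()
    coords: List[np.ndarray] = []
    chain: List[Tuple[int, Optional[int]]] = []
    for r, letter in enumerate(seq):
        bt = ff.backbone_type(letter)
        system.type_names.append(bt)
        system.molecule_ids.append(0)
        system.residue_indices.append(r)
        system.roles.append("backbone")
        coords.append(bb[r])
        b_idx = len(coords) - 1
        st = ff.sidechain_type(letter)
        s_idx = None
        if st is not None:
            radial = bb[r].copy()
            radial[2] = 0.0
            radial /= np.linalg.norm(radial)
            r0 = ff.bond_params(bt, st).r0
            system.type_names.append(st)
            system.molecule_ids.append(0)
            system.residue_indices.append(r)
            system.roles.append("sidechain")
            coords.append(bb[r] + r0 * radial)
            s_idx = len(coords) - 1
        chain.append((b_idx, s_idx))

    pos = np.array(coords)
    # orient along the requested axis and translate to the requested centre
    axis = np.asarray(spec.axis, dtype=float)
    axis /= np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    if np.linalg.norm(v) > 1e-12:
        from scipy.spatial.transform import Rotation
        angle = math.acos(np.clip(np.dot(z, axis), -1.0, 1.0))
        pos = Rotation.from_rotvec(angle * v / np.linalg.norm(v)).apply(pos)
    pos += np.asarray(spec.center, dtype=float)

    system.positions = pos
    _protein_topology(system, ff, [chain])
    return system


# ---------------------------------------------------------------------------
# CG mapping of all-atom structures


def map_structure_to_cg(structure, ff: ForceField,
                        disulfides: Sequence[Tuple[int, int]] = (),
                        missing_cb: str = "bisector") -> CGSystem:
    """Map an all-atom structure to the two-bead-per-residue representation.

    The backbone bead goes to the C-alpha position; the sidechain bead
    is placed on the C-alpha to C-beta ray at the residue-specific bond
    length.  Consecutive residues of the same chain are bonded; separate
    chains stay unbonded.  ``structure`` is a sequence of chains, each a
    list of residues with ``resname`` (3-letter), ``resid`` and an
    ``atoms`` dict of name -> (x, y, z) in nm (see :func:`cgmemsim.io.read_pdb`).

    ``disulfides`` lists pairs of (chain_index, residue_position) tuples
    flattened as global residue order indices of cysteines to bridge.
    ``missing_cb`` selects the fallback for non-Gly residues without a
    C-beta atom: "bisector" places the sidechain along the outward
    bisector of the local backbone angle, "error" raises.
    """
    system = CGSystem()
    coords: List[np.ndarray] = []
    chains_idx: List[List[Tuple[int, Optional[int]]]] = []
    cys_beads: Dict[int, int] = {}
    global_res = 0

    for ci, chain in enumerate(structure):
        chain_pairs: List[Tuple[int, Optional[int]]] = []
        ca_list = []
        for res in chain:
            name3 = res["resname"].upper()
            if name3 not in THREE_TO_ONE:
                raise BuildError(f"unknown residue {name3}")
            if "CA" not in res["atoms"]:
                raise BuildError(f"residue {name3} {res['resid']} has no CA atom")
            ca_list.append(np.asarray(res["atoms"]["CA"], dtype=float))
        for ri, res in enumerate(chain):
            name3 = res["resname"].upper()
            letter = THREE_TO_ONE[name3]
            bt = ff.backbone_type(letter)
            ca = ca_list[ri]
            system.type_names.append(bt)
            system.molecule_ids.append(ci)
            system.residue_indices.append(res["resid"])
            system.roles.append("backbone")
            coords.append(ca)
            b_idx = len(coords) - 1
            st = ff.sidechain_type(letter)
            s_idx = None
            if st is not None:
                r0 = ff.bond_params(bt, st).r0
                if "CB" in res["atoms"]:
                    cb = np.asarray(res["atoms"]["CB"], dtype=float)
                    u = cb - ca
                    u /= np.linalg.norm(u)
                elif missing_cb == "bisector":
                    warnings.warn(
                        f"residue {name3} {res['resid']}: no CB, using backbone "
                        "bisector for the sidechain direction")
                    prev_ca = ca_list[ri - 1] if ri > 0 else None
                    next_ca = ca_list[ri + 1] if ri + 1 < len(ca_list) else None
                    if prev_ca is None and next_ca is None:
                        u = np.array([1.0, 0.0, 0.0])
                    elif prev_ca is None or next_ca is None:
                        other = prev_ca if next_ca is None else next_ca
                        u = ca - other
                        u /= np.linalg.norm(u)
                    else:
                        u = 2 * ca - prev_ca - next_ca
                        norm = np.linalg.norm(u)
                        if norm < 1e-6:  # collinear backbone: any normal works
                            chain_dir = next_ca - prev_ca
                            u = np.cross(chain_dir, [0.0, 0.0, 1.0])
                            if np.linalg.norm(u) < 1e-6:
                                u = np.cross(chain_dir, [1.0, 0.0, 0.0])
                            u /= np.linalg.norm(u)
                        else:
                            u /= norm
                else:
                    raise BuildError(
                        f"residue {name3} {res['resid']}: missing CB atom")
                system.type_names.append(st)
                system.molecule_ids.append(ci)
                system.residue_indices.append(res["resid"])
                system.roles.append("sidechain")
                coords.append(ca + r0 * u)
                s_idx = len(coords) - 1
                if letter == "C":
                    cys_beads[global_res] = s_idx
            chain_pairs.append((b_idx, s_idx))
            global_res += 1
        # split the chain at gaps in residue numbering (missing residues)
        segments: List[List[Tuple[int, Optional[int]]]] = [[chain_pairs[0]]] \
            if chain_pairs else []
        for prev, cur, pair in zip(chain, chain[1:], chain_pairs[1:]):
            if cur["resid"] == prev["resid"] + 1:
                segments[-1].append(pair)
            else:
                segments.append([pair])
        chains_idx.extend(segments)

    system.positions = np.array(coords) if coords else np.zeros((0, 3))
    _protein_topology(system, ff, chains_idx)
    for a, b in disulfides:
        if a not in cys_beads or b not in cys_beads:
            raise BuildError(f"disulfide ({a},{b}) does not name two cysteines")
        system.bonds.append((cys_beads[a], cys_beads[b], ff.bond_params("SC", "SC")))
    return system


# ---------------------------------------------------------------------------
# membranes and solvent

LIPID_TOPOLOGIES = {"H4T3T3": (4, 3), "H4T4T4": (4, 4)}

LIPID_BOND = 0.33  # nm between consecutive lipid beads
TAIL_SEP = 0.45  # nm lateral separation of the two tails of one lipid
TIP_Z = 0.20  # nm, distance of the deepest tail bead from the midplane


def _single_lipid(ff: ForceField, n_tail: int, leaflet: int,
                  xy: Tuple[float, float], stiffened: bool) -> CGSystem:
    """One lipid: 4 head beads and two tails, pointing toward z = 0."""
    s = 1.0 if leaflet > 0 else -1.0
    x0, y0 = xy
    k = ff.harmonic_angles["lipid-tail"].k_theta * (2.0 if stiffened else 1.0)
    ang = HarmonicAngleParams(math.pi, k)

    pos: List[List[float]] = []
    types: List[str] = []
    roles: List[str] = []
    z1 = TIP_Z + n_tail * LIPID_BOND  # z of the tail-anchoring head beads
    # head beads: H1-H2 stacked above the two anchors H3, H4
    half = TAIL_SEP / 2.0
    head_xy = [(x0 - half, y0), (x0 - half, y0), (x0 - half, y0), (x0 + half, y0)]
    head_z = [z1 + 2 * LIPID_BOND, z1 + LIPID_BOND, z1, z1]
    for (hx, hy), hz in zip(head_xy, head_z):
        pos.append([hx, hy, s * hz])
        types.append("H")
        roles.append("lipid-head")
    # tails: A under H3 (index 2), B under H4 (index 3)
    tails = []
    for t, xoff in ((0, -half), (1, half)):
        first = len(pos)
        for b in range(n_tail):
            pos.append([x0 + xoff, y0, s * (z1 - (b + 1) * LIPID_BOND)])
            types.append("T")
            roles.append("lipid-tail")
        tails.append(list(range(first, first + n_tail)))

    sys1 = CGSystem(
        type_names=types,
        positions=np.array(pos),
        molecule_ids=[0] * len(pos),
        residue_indices=[0] * len(pos),
        roles=roles,
    )
    bp_hh = ff.bond_params("H", "H")
    bp_ht = ff.bond_params("H", "T")
    bp_tt = ff.bond_params("T", "T")
    sys1.bonds = [(0, 1, bp_hh), (1, 2, bp_hh), (2, 3, bp_hh)]
    for anchor, tail in zip((2, 3), tails):
        sys1.bonds.append((anchor, tail[0], bp_ht))
        for a, b in zip(tail, tail[1:]):
            sys1.bonds.append((a, b, bp_tt))
        chain = [anchor] + tail
        for a, b, c in zip(chain, chain[1:], chain[2:]):
            sys1.harmonic_angles.append((a, b, c, ang))
    return sys1


def build_membrane(lipid_code: str, area: float, ff: ForceField,
                   area_per_lipid: float = 0.65,
                   stiffened_tails: bool = False) -> CGSystem:
    """Two-leaflet bilayer on a staggered square lattice in the xy plane.

    ``area`` is the target xy area in nm^2 (the box is made square);
    ``area_per_lipid`` sets the lateral lipid density.  With
    ``stiffened_tails`` the tail angle constant is doubled (the rigid
    membrane control).
    """
    if lipid_code not in LIPID_TOPOLOGIES:
        raise BuildError(
            f"unknown lipid code {lipid_code!r}; known: {sorted(LIPID_TOPOLOGIES)}")
    _, n_tail = LIPID_TOPOLOGIES[lipid_code]
    spacing = math.sqrt(area_per_lipid)
    n_side = int(round(math.sqrt(area) / spacing))
    if n_side * n_side < 4:
        raise BuildError("area accommodates fewer than 4 lipids per leaflet")
    L = n_side * spacing

    membrane = CGSystem()
    mol = 0
    parts: List[CGSystem] = []
    for leaflet in (+1, -1):
        for iy in range(n_side):
            for ix in range(n_side):
                x = (ix + 0.5) * spacing + (0.25 * spacing if iy % 2 else 0.0)
                y = (iy + 0.5) * spacing
                lip = _single_lipid(ff, n_tail, leaflet,
                                    (x % L, y % L), stiffened_tails)
                parts.append(lip)
                mol += 1
    for lip in parts:
        membrane = membrane.merge(lip)
    lipid_height = TIP_Z + (n_tail + 2) * LIPID_BOND
    membrane.box = np.array([L, L, 2 * lipid_height + 2.0])
    membrane.periodic = (True, True, True)
    return membrane


def _water_lattice(box: np.ndarray, spacing: float) -> np.ndarray:
    nums = np.maximum((box / spacing).astype(int), 1)
    grids = [(np.arange(n) + 0.5) * (L / n) for n, L in zip(nums, box)]
    xx, yy, zz = np.meshgrid(*grids, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])


def solvate_and_embed(membrane: CGSystem, ff: ForceField,
                      peptide: Optional[CGSystem] = None,
                      water_margin: float = 1.2,
                      water_spacing: float = 0.45,
                      overlap_factor: float = 0.9) -> CGSystem:
    """Insert a peptide transmembrane, prune overlapping lipids, add water.

    The peptide (if any) is centred on the bilayer midplane with its
    axis along z (callers build it that way); lipids with any bead
    closer than ``overlap_factor`` times the contact distance to a
    peptide bead are removed, then water beads fill the remaining volume
    on a lattice with the same overlap criterion.
    """
    box = membrane.box.copy()
    zmax = float(np.abs(membrane.positions[:, 2]).max())
    box[2] = 2 * (zmax + water_margin)
    center = np.array([box[0] / 2, box[1] / 2, 0.0])

    solute = CGSystem(box=box, periodic=(True, True, True))
    if peptide is not None and peptide.n_particles:
        xy_shift = center - peptide.positions.mean(axis=0)
        xy_shift[2] = 0.0  # keep the hydrophobic centre on the midplane
        peptide = _shift(peptide, xy_shift)
        if np.ptp(peptide.positions[:, 2]) > box[2] - 0.4:
            raise BuildError("peptide does not fit in the solvated box")
        solute = solute.merge(peptide)

    radii = {t: ff.particle_types[t].radius for t in ff.particle_types}

    def overlaps(pos, types, against_pos, against_types):
        if len(against_pos) == 0:
            return np.zeros(len(pos), dtype=bool)
        out = np.zeros(len(pos), dtype=bool)
        arad = np.array([radii[t] for t in against_types])
        for idx, (p, t) in enumerate(zip(pos, types)):
            d = against_pos - p
            d -= np.round(d / box) * box
            r = np.linalg.norm(d, axis=1)
            if np.any(r < overlap_factor * (radii[t] + arad)):
                out[idx] = True
        return out

    # prune whole lipids clashing with the peptide
    keep = CGSystem(box=box, periodic=(True, True, True))
    n_mol = max(membrane.molecule_ids, default=-1) + 1
    sol_pos = solute.positions
    sol_types = solute.type_names
    mol_of = np.array(membrane.molecule_ids)
    clash = overlaps(membrane.positions, membrane.type_names, sol_pos, sol_types)
    bad_mols = set(mol_of[clash])
    keep = _subset_molecules(membrane, [m for m in range(n_mol) if m not in bad_mols])
    keep.box = box
    system = solute.merge(keep) if solute.n_particles else keep
    system.box = box
    system.periodic = (True, True, True)

    # fill with water where there is room (z centred on the midplane)
    wpos = _water_lattice(box, water_spacing)
    wpos[:, 2] -= box[2] / 2.0
    wclash = overlaps(wpos, ["W"] * len(wpos), system.positions, system.type_names)
    wpos = wpos[~wclash]
    water = CGSystem(
        type_names=["W"] * len(wpos),
        positions=wpos,
        molecule_ids=list(range(len(wpos))),
        residue_indices=[0] * len(wpos),
        roles=["water"] * len(wpos),
        box=box, periodic=(True, True, True),
    )
    out = system.merge(water)
    out.box = box
    out.periodic = (True, True, True)
    return out


def _shift(system: CGSystem, delta) -> CGSystem:
    import copy
    out = copy.copy(system)
    out.positions = system.positions + np.asarray(delta)
    return out


def _subset_molecules(system: CGSystem, mols: Sequence[int]) -> CGSystem:
    mols = set(mols)
    idx = [i for i, m in enumerate(system.molecule_ids) if m in mols]
    remap = {old: new for new, old in enumerate(idx)}
    out = CGSystem(
        type_names=[system.type_names[i] for i in idx],
        positions=system.positions[idx],
        molecule_ids=[system.molecule_ids[i] for i in idx],
        residue_indices=[system.residue_indices[i] for i in idx],
        roles=[system.roles[i] for i in idx],
        box=system.box.copy(),
        periodic=system.periodic,
    )
    out.bonds = [(remap[i], remap[j], p) for i, j, p in system.bonds
                 if i in remap and j in remap]
    out.harmonic_angles = [(remap[i], remap[j], remap[k], p)
                           for i, j, k, p in system.harmonic_angles
                           if i in remap and j in remap and k in remap]
    out.double_angles = [(remap[i], remap[j], remap[k], p)
                         for i, j, k, p in system.double_angles
                         if i in remap and j in remap and k in remap]
    return out
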