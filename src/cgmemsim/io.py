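"""File formats: all-atom PDB input, CG PDB dialect + topology JSON,
multi-frame XYZ trajectories, TSV tables and run manifests.

The CG structure file is a PDB dialect with one ATOM record per bead
(bead code in the atom-name field, molecule id mapped to the chain
column, element blank).  PDB cannot carry double-well angle terms, so
the bonded topology travels in a JSON sidecar.
"""

from __future__ import annotations

import hashlib
import json
import string
import warnings
from dataclasses import asdict, dataclass
from typing import Dict, Optional

import numpy as np

from . import __version__
from .builder import CGSystem, THREE_TO_ONE
from .forcefield import BondParams, DoubleAngleParams, HarmonicAngleParams

__all__ = [
    "read_pdb",
    "write_cg_pdb",
    "write_topology",
    "read_cg_system",
    "write_xyz_trajectory",
    "read_xyz_trajectory",
    "write_tsv",
    "RunManifest",
    "PDBError",
]


class PDBError(ValueError):
    pass


def read_pdb(path):
    """Parse an all-atom PDB file into the builder's chain/residue structure.

    Returns a list of chains; each chain is a list of residue dicts with
    ``resname`` (3-letter code), ``resid`` and ``atoms`` mapping atom
    names to (x, y, z) in nm.  Only standard amino-acid residues with a
    CA atom are kept; altloc variants resolve to the highest occupancy;
    gaps in residue numbering (missing residues) are reported via a
    warning, never fabricated.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    try:
        model = parser.get_structure("s", str(path))[0]
    except Exception as exc:
        raise PDBError(f"{path}: cannot parse PDB file ({exc})") from None

    chains = []
    gaps = []
    for chain in model:
        residues = []
        prev = None
        for res in chain:
            hetfield, resid, _ = res.get_id()
            if hetfield.strip():
                continue  # heteroatoms/waters
            name3 = res.get_resname().upper()
            if name3 not in THREE_TO_ONE:
                continue
            atoms = {}
            for atom in res:  # disordered atoms yield highest occupancy
                atoms[atom.get_name()] = tuple(atom.coord / 10.0)
            if "CA" not in atoms:
                warnings.warn(f"residue {name3} {resid}: no CA atom, skipped")
                continue
            if prev is not None and resid != prev + 1:
                gaps.append((chain.id, prev, resid))
            prev = resid
            residues.append({"resname": name3, "resid": resid, "atoms": atoms})
        if residues:
            chains.append(residues)
    if not chains:
        raise PDBError(f"{path}: no amino-acid residues with CA atoms")
    if gaps:
        warnings.warn(f"missing residues at {gaps} (left out, not modeled)")
    return chains


_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def write_cg_pdb(system: CGSystem, path) -> None:
    """One ATOM record per bead; coordinates nm -> Angstrom."""
    with open(path, "w") as fh:
        fh.write("REMARK   coarse-grained bead model (cgmemsim dialect)\n")
        fh.write("CRYST1{:9.3f}{:9.3f}{:9.3f}  90.00  90.00  90.00 P 1\n".format(
            *(10.0 * system.box)))
        for i in range(system.n_particles):
            x, y, z = 10.0 * system.positions[i]
            chain = _CHAIN_IDS[system.molecule_ids[i] % len(_CHAIN_IDS)]
            fh.write(
                "ATOM  {serial:>5d} {name:<4s} CG  {chain}{resid:>4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n".format(
                    serial=(i + 1) % 100000,
                    name=system.type_names[i][:4],
                    chain=chain,
                    resid=system.residue_indices[i] % 10000,
                    x=x, y=y, z=z))
        fh.write("END\n")


def write_topology(system: CGSystem, path) -> None:
    data = {
        "type_names": system.type_names,
        "molecule_ids": system.molecule_ids,
        "residue_indices": system.residue_indices,
        "roles": system.roles,
        "box": list(map(float, system.box)),
        "periodic": list(system.periodic),
        "bonds": [[i, j, p.r0, p.k] for i, j, p in system.bonds],
        "harmonic_angles": [[i, j, k, p.theta0, p.k_theta]
                            for i, j, k, p in system.harmonic_angles],
        "double_angles": [[i, j, k, p.theta1, p.theta2, p.V1, p.V2, p.Vbar]
                          for i, j, k, p in system.double_angles],
    }
    with open(path, "w") as fh:
        json.dump(data, fh)


def read_cg_system(pdb_path, topology_path) -> CGSystem:
    """Load a CG structure + topology sidecar back into a CGSystem."""
    with open(topology_path) as fh:
        top = json.load(fh)
    positions = []
    with open(pdb_path) as fh:
        for line in fh:
            if line.startswith("ATOM"):
                positions.append([float(line[30:38]) / 10.0,
                                  float(line[38:46]) / 10.0,
                                  float(line[46:54]) / 10.0])
    pos = np.array(positions)
    if len(pos) != len(top["type_names"]):
        raise PDBError("structure and topology disagree on bead count")
    da_cache: Dict[tuple, DoubleAngleParams] = {}

    def da(params):
        key = tuple(params)
        if key not in da_cache:
            da_cache[key] = DoubleAngleParams(*params)
        return da_cache[key]

    return CGSystem(
        type_names=list(top["type_names"]),
        positions=pos,
        molecule_ids=list(top["molecule_ids"]),
        residue_indices=list(top["residue_indices"]),
        roles=list(top["roles"]),
        bonds=[(i, j, BondParams(r0, k)) for i, j, r0, k in top["bonds"]],
        harmonic_angles=[(i, j, k, HarmonicAngleParams(t0, kt))
                         for i, j, k, t0, kt in top["harmonic_angles"]],
        double_angles=[(i, j, k, da(rest))
                       for i, j, k, *rest in top["double_angles"]],
        box=np.array(top["box"], dtype=float),
        periodic=tuple(bool(p) for p in top["periodic"]),
    )


def write_xyz_trajectory(frames, system: CGSystem, path) -> None:
    """Plain multi-frame XYZ; the comment line carries step, time and box."""
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(f"{len(fr.positions)}\n")
            fh.write("step={} time_ps={:.6f} box={:.6f},{:.6f},{:.6f}\n".format(
                fr.step, fr.time, *fr.box))
            for name, p in zip(system.type_names, fr.positions):
                fh.write(f"{name} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def read_xyz_trajectory(path):
    """Yield (step, time, box, positions) tuples from a trajectory file."""
    out = []
    with open(path) as fh:
        while True:
            head = fh.readline()
            if not head.strip():
                break
            n = int(head)
            meta = fh.readline().split()
            kv = dict(item.split("=") for item in meta)
            box = np.array([float(v) for v in kv["box"].split(",")])
            pos = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                pos[i] = [float(v) for v in parts[1:4]]
            out.append((int(kv["step"]), float(kv["time_ps"]), box, pos))
    return out


def write_tsv(path, columns: Dict[str, np.ndarray]) -> None:
    names = list(columns)
    arr = np.column_stack([np.asarray(columns[c], dtype=float) for c in names])
    np.savetxt(path, arr, delimiter="\t", header="\t".join(names), comments="")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-run a simulation bit-identically."""

    config: Dict
    seed: int
    code_version: str
    forcefield_sha256: Optional[str] = None
    input_sha256: Optional[Dict[str, str]] = None

    @classmethod
    def create(cls, config, seed, forcefield_path=None, inputs=()):
        return cls(
            config=dict(config),
            seed=int(seed),
            code_version=__version__,
            forcefield_sha256=_sha256(forcefield_path) if forcefield_path else None,
            input_sha256={str(p): _sha256(p) for p in inputs} or None,
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
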