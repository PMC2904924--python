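"""Deterministic miniature systems with analytically known observables.

These are the package's test and demonstration fixtures: every fixture
builds in well under a second and ships a sidecar dict of expected
values computed from the construction geometry (not from simulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .builder import (
    CGSystem,
    PeptideSpec,
    build_membrane,
    build_walp,
    solvate_and_embed,
    walp_sequence,
    LIPID_BOND,
    TIP_Z,
    LIPID_TOPOLOGIES,
)
from .forcefield import ForceField, default_forcefield

__all__ = ["FixtureSpec", "make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("mini-bilayer", "helix", "probe-pull", "walp-sweep")


@dataclass
class FixtureSpec:
    name: str
    size: Dict[str, float] = field(default_factory=dict)
    seed: int = 0


def make_fixture(spec: FixtureSpec, ff: ForceField = None
                 ) -> Tuple[CGSystem, Dict]:
    """Build a named fixture; returns (system, expected-value sidecar)."""
    if ff is None:
        ff = default_forcefield()
    if spec.name == "helix":
        n = int(spec.size.get("n", 16))
        system = build_walp(PeptideSpec(walp_sequence(n)), ff)
        bb = system.positions[system.backbone_indices()]
        sidecar = {
            "i_i4_distances": np.linalg.norm(bb[4:] - bb[:-4], axis=1).tolist(),
            "bond_lengths": np.linalg.norm(bb[1:] - bb[:-1], axis=1).tolist(),
            "n_backbone": len(bb),
        }
        return system, sidecar
    if spec.name == "mini-bilayer":
        code = spec.size.get("lipid", "H4T4T4")
        area = float(spec.size.get("area", 16.0))
        system = build_membrane(code, area, ff)
        n_tail = LIPID_TOPOLOGIES[code][1]
        z_first_tail = TIP_Z + (n_tail - 1) * LIPID_BOND
        sidecar = {
            "expected_thickness": 2.0 * z_first_tail,
            "lipids_per_leaflet": max(system.molecule_ids) // 2 + 1
            if system.molecule_ids else 0,
        }
        return system, sidecar
    if spec.name == "probe-pull":
        code = spec.size.get("lipid", "H4T4T4")
        area = float(spec.size.get("area", 9.0))
        probe_type = spec.size.get("probe", "SL")
        membrane = build_membrane(code, area, ff)
        zmax = float(np.abs(membrane.positions[:, 2]).max())
        # the probe starts in the water phase below the membrane
        probe = CGSystem(
            type_names=[str(probe_type)],
            positions=np.array([[0.0, 0.0, -(zmax + 0.7)]]),
            molecule_ids=[0], residue_indices=[0], roles=["sidechain"],
        )
        out = solvate_and_embed(membrane, ff, peptide=probe, water_margin=1.4)
        return out, {"probe_index": 0}
    if spec.name == "walp-sweep":
        n = int(spec.size.get("n", 23))
        code = spec.size.get("lipid", "H4T3T3")
        area = float(spec.size.get("area", 25.0))
        margin = float(spec.size.get("water_margin", 1.2))
        pep = build_walp(PeptideSpec(walp_sequence(n)), ff)
        membrane = build_membrane(code, area, ff,
                                  stiffened_tails=bool(
                                      spec.size.get("stiffened", False)))
        # make room for long peptides
        half_pep = 0.5 * float(np.ptp(pep.positions[:, 2]))
        zmax = float(np.abs(membrane.positions[:, 2]).max())
        margin = max(margin, half_pep - zmax + 0.8)
        system = solvate_and_embed(membrane, ff, peptide=pep,
                                   water_margin=margin)
        n_bb = n
        sidecar = {"peptide_backbone": [
            i for i in range(system.n_particles)
            if system.roles[i] == "backbone"][:n_bb]}
        return system, sidecar
    raise ValueError(f"unknown fixture {spec.name!r}; known: {FIXTURE_NAMES}")
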