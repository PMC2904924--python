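"""Trajectory observables: CRMS-alpha, radius of gyration, hydrogen-bond
distance distributions, the local membrane-thickness grid, hydrophobic
mismatch, membrane adaptation and peptide tilt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.stats import spearmanr  # noqa: F401  (re-exported for sweep analyses)

from .builder import CGSystem
from .engine import Trajectory

__all__ = [
    "crms_alpha",
    "radius_of_gyration",
    "hbond_pair_distributions",
    "membrane_thickness_grid",
    "mismatch_report",
    "ThicknessGrid",
    "MismatchResult",
    "helix_axis_and_dp",
    "tilt_angle",
]


def crms_alpha(coords: np.ndarray, reference: np.ndarray,
               superpose: bool = True) -> float:
    """Coordinate RMS deviation of backbone beads from a reference (nm).

    By default the frame is first optimally superposed onto the
    reference (rigid rotation plus translation), so whole-body diffusion
    of the molecule does not contribute; pass ``superpose=False`` for
    the raw deviation in the laboratory frame.
    """
    coords = np.asarray(coords, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if coords.shape != reference.shape:
        raise ValueError("frame and reference differ in bead count")
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 backbone beads")
    if superpose:
        x = coords - coords.mean(axis=0)
        y = reference - reference.mean(axis=0)
        _, rssd = Rotation.align_vectors(y, x)
        return float(rssd / math.sqrt(len(x)))
    return float(np.sqrt(((coords - reference) ** 2).sum(axis=1).mean()))


def radius_of_gyration(coords: np.ndarray) -> float:
    """Unweighted RMS distance of beads to their geometric centre (nm)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("need at least one bead")
    d = coords - coords.mean(axis=0)
    return float(np.sqrt((d * d).sum(axis=1).mean()))


def hbond_pair_distributions(
        trajectory: Iterable[np.ndarray], offsets: Sequence[int] = (3, 4, 5),
        bins: Optional[np.ndarray] = None,
) -> Dict[int, Tuple[np.ndarray, np.ndarray]]:
    """Histograms of backbone i,i+k distances for helix hydrogen-bond registers.

    ``trajectory`` yields (n_backbone, 3) coordinate arrays of one
    peptide's backbone beads in chain order.  Offsets 3/4/5 probe the
    tighter-helix, alpha-helix and wider-helix hydrogen-bond registers.
    Returns ``{offset: (density, bin_edges)}`` with densities normalised
    to unit integral; an empty histogram is returned for offsets longer
    than the chain.
    """
    if bins is None:
        bins = np.arange(0.2, 2.5, 0.005)
    samples: Dict[int, List[np.ndarray]] = {k: [] for k in offsets}
    n_frames = 0
    for bb in trajectory:
        bb = np.asarray(bb, dtype=float)
        n_frames += 1
        for k in offsets:
            if bb.shape[0] > k:
                d = np.linalg.norm(bb[k:] - bb[:-k], axis=1)
                samples[k].append(d)
    if n_frames == 0:
        raise ValueError("empty trajectory")
    out = {}
    for k in offsets:
        if samples[k]:
            data = np.concatenate(samples[k])
            hist, edges = np.histogram(data, bins=bins, density=True)
        else:
            hist, edges = np.zeros(len(bins) - 1), np.asarray(bins)
        out[k] = (hist, edges)
    return out


def histogram_mode(hist: np.ndarray, edges: np.ndarray) -> float:
    """Centre of the most populated histogram bin."""
    i = int(np.argmax(hist))
    return float(0.5 * (edges[i] + edges[i + 1]))


@dataclass
class ThicknessGrid:
    """Local bilayer thickness on an n x n grid over the xy box."""

    thickness: np.ndarray  # (n, n), nm; NaN for empty sections
    counts: np.ndarray  # (n, n) lipids per section
    box_xy: Tuple[float, float]

    @property
    def mean_thickness(self) -> float:
        return float(np.nanmean(self.thickness))

    def far_field(self, center_xy, r_far: float) -> float:
        """Mean thickness of sections whose centre is beyond r_far of a point."""
        return self._masked_mean(center_xy, r_far, np.inf)

    def near_field(self, center_xy, r_near: float) -> float:
        """Mean thickness of sections whose centre is within r_near of a point."""
        return self._masked_mean(center_xy, 0.0, r_near)

    def _masked_mean(self, center_xy, rmin, rmax) -> float:
        n = self.thickness.shape[0]
        lx, ly = self.box_xy
        cx = (np.arange(n) + 0.5) * lx / n
        cy = (np.arange(n) + 0.5) * ly / n
        dx = cx[:, None] - center_xy[0]
        dy = cy[None, :] - center_xy[1]
        dx -= lx * np.round(dx / lx)
        dy -= ly * np.round(dy / ly)
        r = np.hypot(dx, dy)
        mask = (r >= rmin) & (r <= rmax) & ~np.isnan(self.thickness)
        if not mask.any():
            return float("nan")
        return float(self.thickness[mask].mean())


def first_tail_bead_indices(system: CGSystem) -> np.ndarray:
    """Tail beads directly bonded to a head bead (the thickness markers)."""
    head = {i for i, r in enumerate(system.roles) if r == "lipid-head"}
    tail = {i for i, r in enumerate(system.roles) if r == "lipid-tail"}
    first = set()
    for i, j, _ in system.bonds:
        if i in head and j in tail:
            first.add(j)
        elif j in head and i in tail:
            first.add(i)
    return np.array(sorted(first), dtype=np.int64)


def membrane_thickness_grid(positions: np.ndarray, box: np.ndarray,
                            first_tails: np.ndarray,
                            n_sections: int = 17) -> ThicknessGrid:
    """Local membrane thickness per grid section.

    Each lipid contributes its head-adjacent (first) tail beads; a bead
    in a section contributes twice its |z| distance to that section's
    midplane (the mean z of the section's first-tail beads over both
    leaflets), and the section thickness is the mean over its beads.
    """
    if len(first_tails) == 0:
        raise ValueError("no lipids in system")
    lx, ly = float(box[0]), float(box[1])
    xy = positions[first_tails, :2] % np.array([lx, ly])
    z = positions[first_tails, 2]
    upper = z >= np.median(z)  # leaflet assignment via the global midplane
    ix = np.minimum((xy[:, 0] / lx * n_sections).astype(int), n_sections - 1)
    iy = np.minimum((xy[:, 1] / ly * n_sections).astype(int), n_sections - 1)
    thick = np.full((n_sections, n_sections), np.nan)
    counts = np.zeros((n_sections, n_sections), dtype=int)
    for a in range(n_sections):
        for b in range(n_sections):
            sel = (ix == a) & (iy == b)
            counts[a, b] = int(sel.sum())
            up, dn = sel & upper, sel & ~upper
            # a section needs beads from both leaflets for its midplane
            # to be meaningful; others stay flagged (NaN)
            if up.any() and dn.any():
                zmid = 0.5 * (z[up].mean() + z[dn].mean())
                thick[a, b] = float(2.0 * np.abs(z[sel] - zmid).mean())
    return ThicknessGrid(thick, counts, (lx, ly))


@dataclass
class MismatchResult:
    dP: float  # nm, peptide hydrophobic length
    dL: float  # nm, far-field membrane hydrophobic thickness
    mismatch: float  # nm, dP - dL
    adaptation: float  # nm, near-field minus far-field thickness
    tilt: float  # degrees in [0, 90]


def helix_axis_and_dp(backbone: np.ndarray, n_terminal: int = 4):
    """Axis vector and hydrophobic length from the two terminal centroids.

    The hydrophobic length is the distance between the mean positions
    of the first and last ``n_terminal`` backbone beads (the flanking
    residues are non-lipophilic); the helical axis is the vector joining
    those centroids.
    """
    backbone = np.asarray(backbone, dtype=float)
    if backbone.shape[0] < 2 * n_terminal:
        raise ValueError(f"need at least {2 * n_terminal} backbone beads")
    a = backbone[:n_terminal].mean(axis=0)
    b = backbone[-n_terminal:].mean(axis=0)
    axis = b - a
    dp = float(np.linalg.norm(axis))
    if dp < 1e-9:
        raise ValueError("degenerate helical axis: terminal centroids coincide")
    return axis / dp, dp


def tilt_angle(axis: np.ndarray) -> float:
    """Angle (degrees) between an axis and the membrane normal (+z), in [0, 90]."""
    c = abs(float(axis[2]) / float(np.linalg.norm(axis)))
    return math.degrees(math.acos(min(1.0, c)))


def mismatch_report(trajectory: Trajectory, system: CGSystem,
                    peptide_backbone: np.ndarray,
                    window: float = 240.0,
                    r_near: float = 1.5, r_far: float = 3.0,
                    n_sections: int = 17) -> MismatchResult:
    """Hydrophobic mismatch, membrane adaptation and tilt, time-averaged.

    Averages run over the trajectory frames inside the final ``window``
    picoseconds.  ``peptide_backbone`` indexes the peptide's backbone
    beads in chain order.  Near field: grid sections within ``r_near``
    nm of the peptide axis xy position; far field: beyond ``r_far`` nm.
    """
    if len(peptide_backbone) < 8:
        raise ValueError("peptide too short for mismatch analysis")
    first_tails = first_tail_bead_indices(system)
    # in small patches "far" cannot exceed the half-box; clamp so a far
    # field always exists (the periodic corners)
    half_box = 0.5 * float(min(trajectory[-1].box[0], trajectory[-1].box[1]))
    r_far = min(r_far, half_box - 0.2)
    r_near = min(r_near, r_far - 0.3)
    t_end = trajectory[-1].time
    frames = [f for f in trajectory if f.time >= t_end - window]
    dps, dls, adapts, tilts = [], [], [], []
    for fr in frames:
        bb = fr.positions[peptide_backbone]
        axis, dp = helix_axis_and_dp(bb)
        grid = membrane_thickness_grid(fr.positions, fr.box, first_tails,
                                       n_sections)
        center_xy = bb.mean(axis=0)[:2] % np.array([fr.box[0], fr.box[1]])
        far = grid.far_field(center_xy, r_far)
        near = grid.near_field(center_xy, r_near)
        dps.append(dp)
        dls.append(far)
        adapts.append(near - far)
        tilts.append(tilt_angle(axis))
    dp = float(np.mean(dps))
    dl = float(np.nanmean(dls))
    return MismatchResult(
        dP=dp, dL=dl, mismatch=dp - dl,
        adaptation=float(np.nanmean(adapts)),
        tilt=float(np.mean(tilts)),
    )
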