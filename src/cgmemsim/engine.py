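"""MD engine: neighbor-listed forces, leapfrog integration, Berendsen
temperature/pressure coupling and steered (phantom-spring) pulls.

The integrator is leapfrog with a 12 fs default step.  Temperature is
controlled by Berendsen velocity rescaling and pressure by Berendsen
box rescaling; for membrane systems the barostat is semi-isotropic
(x and y coupled together, z independent), for solution systems it is
isotropic.  Setting ``tau_T`` / ``tau_P`` to ``None`` turns the
respective coupling off (NVE when both are off).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _kernels as K
from .builder import CGSystem
from .forcefield import ForceField
from .units import ATM, KB

__all__ = [
    "SimulationConfig",
    "PullSpec",
    "Frame",
    "Trajectory",
    "compute_forces",
    "minimize_energy",
    "run_md",
    "steered_pull",
    "SimulationError",
]

_STYLE_CODE = {"LJ": 0, "WCA": 1, "LJHB": 2}


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    dt: float = 0.012  # ps (12 fs leapfrog step)
    temperature: float = 324.0  # K
    pressure: float = 1.0  # atm
    tau_T: Optional[float] = 0.1  # ps; None disables the thermostat
    tau_P: Optional[float] = None  # ps; None disables the barostat
    compressibility: float = 4.5e-5  # atm^-1
    cutoff: float = 1.2  # nm
    neighbor_skin: float = 0.3  # nm
    n_steps: int = 1000
    seed: int = 0
    output_stride: int = 100
    barostat_mode: str = "semiisotropic"  # or "isotropic"

    def validate(self, box: np.ndarray, periodic) -> None:
        if self.dt <= 0:
            raise SimulationError("dt must be positive")
        if any(periodic):
            half = min(b for b, p in zip(box, periodic) if p) / 2
            if self.cutoff + self.neighbor_skin >= half:
                raise SimulationError(
                    "cutoff + skin must be below half the smallest periodic "
                    f"box length ({half:.3f} nm)")


@dataclass
class PullSpec:
    """Constant-velocity pull of target particles via a phantom spring."""

    targets: Sequence[int]
    spring_k: float = 100.0  # kJ/mol/nm^2
    velocity: float = 0.002  # nm/ps
    axis: Tuple[float, float, float] = (0.0, 0.0, 1.0)
    start: Optional[Tuple[float, float, float]] = None

    def __post_init__(self):
        if self.spring_k <= 0:
            raise SimulationError("pull spring constant must be positive")
        if abs(self.velocity) <= 0:
            raise SimulationError("pull velocity must be nonzero")


@dataclass
class Frame:
    step: int
    time: float
    positions: np.ndarray
    box: np.ndarray
    temperature: float
    energies: Dict[str, float]
    pull: Optional[Dict[str, float]] = None

    def __post_init__(self):
        if not all(np.isfinite(v) for v in self.energies.values()):
            raise SimulationError(f"non-finite energies at step {self.step}")


Trajectory = List[Frame]


class _Arrays:
    """System compiled to flat arrays plus per-type-pair matrices."""

    def __init__(self, system: CGSystem, ff: ForceField, cutoff: float):
        self.system = system
        n = system.n_particles
        names = sorted(set(system.type_names))
        self.type_of = {t: i for i, t in enumerate(names)}
        self.tidx = np.array([self.type_of[t] for t in system.type_names],
                             dtype=np.int64)
        nt = len(names)
        self.style = np.zeros((nt, nt), dtype=np.int64)
        self.eps = np.zeros((nt, nt))
        self.sig = np.zeros((nt, nt))
        self.shift = np.zeros((nt, nt))
        for a in names:
            for b in names:
                p = ff.pair_params(a, b)
                i, j = self.type_of[a], self.type_of[b]
                self.style[i, j] = _STYLE_CODE[p.style]
                self.eps[i, j] = p.epsilon
                self.sig[i, j] = p.sigma
                if p.style != "WCA":
                    s6 = (p.sigma / cutoff) ** 6
                    self.shift[i, j] = 4 * p.epsilon * (s6 * s6 - s6)
        self.mu, self.kappa, self.eta = ff.ljhb_mu, ff.ljhb_kappa, ff.ljhb_eta

        self.masses = system.masses(ff)
        bl = system.bonds
        self.bond_i = np.array([b[0] for b in bl], dtype=np.int64)
        self.bond_j = np.array([b[1] for b in bl], dtype=np.int64)
        self.bond_r0 = np.array([b[2].r0 for b in bl])
        self.bond_k = np.array([b[2].k for b in bl])
        ha = system.harmonic_angles
        self.ha_i = np.array([a[0] for a in ha], dtype=np.int64)
        self.ha_j = np.array([a[1] for a in ha], dtype=np.int64)
        self.ha_k = np.array([a[2] for a in ha], dtype=np.int64)
        self.ha_t0 = np.array([a[3].theta0 for a in ha])
        self.ha_kt = np.array([a[3].k_theta for a in ha])
        da = system.double_angles
        self.da_i = np.array([a[0] for a in da], dtype=np.int64)
        self.da_j = np.array([a[1] for a in da], dtype=np.int64)
        self.da_k = np.array([a[2] for a in da], dtype=np.int64)
        self.da_t1 = np.array([a[3].theta1 for a in da])
        self.da_t2 = np.array([a[3].theta2 for a in da])
        self.da_xi = np.array([a[3].xi for a in da])
        self.da_A = np.array([a[3].A for a in da])
        self.da_D = np.array([a[3].D for a in da])

        excl = system.exclusion_pairs()
        per: Dict[int, List[int]] = {i: [] for i in range(n)}
        for i, j in excl:
            per[i].append(j)
            per[j].append(i)
        m = max((len(v) for v in per.values()), default=1) or 1
        self.excl = np.full((n, m), -1, dtype=np.int64)
        for i, lst in per.items():
            for e, j in enumerate(sorted(lst)):
                self.excl[i, e] = j

    def effective_box(self, system: CGSystem) -> np.ndarray:
        """Box with non-periodic axes inflated so no image is ever applied."""
        box = system.box.astype(float).copy()
        for ax in range(3):
            if not system.periodic[ax]:
                box[ax] = 1e6
        return box


def _evaluate(arr: _Arrays, pos, box, pairs, n_pairs, cutoff):
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    virial = np.zeros(3)
    e_lj, e_hb = K.nonbonded_forces(
        pos, box, pairs, n_pairs, arr.tidx, arr.style, arr.eps, arr.sig,
        arr.shift, arr.mu, arr.kappa, arr.eta, cutoff, forces, virial)
    e_bond = K.bond_forces(pos, box, arr.bond_i, arr.bond_j, arr.bond_r0,
                           arr.bond_k, forces, virial)
    e_ha = K.harmonic_angle_forces(pos, box, arr.ha_i, arr.ha_j, arr.ha_k,
                                   arr.ha_t0, arr.ha_kt, forces, virial)
    e_da = K.double_angle_forces(pos, box, arr.da_i, arr.da_j, arr.da_k,
                                 arr.da_t1, arr.da_t2, arr.da_xi, arr.da_A,
                                 arr.da_D, forces, virial)
    energies = {"lj": e_lj, "ljhb": e_hb, "bond": e_bond,
                "harmonic_angle": e_ha, "double_angle": e_da,
                "potential": e_lj + e_hb + e_bond + e_ha + e_da}
    return forces, energies, virial


def _neighbor_pairs(arr: _Arrays, pos, box, rlist):
    n = pos.shape[0]
    max_pairs = max(64 * n, 4096)
    while True:
        pairs, count = K.build_neighbor_list(pos, box, rlist, arr.excl, max_pairs)
        if count >= 0:
            return pairs, count
        max_pairs *= 2


def compute_forces(system: CGSystem, ff: ForceField, cutoff: float = 1.2,
                   all_pairs: bool = False, neighbor_skin: float = 0.3):
    """Forces (kJ/mol/nm) and per-term energy breakdown for one configuration.

    With ``all_pairs`` the neighbor search radius covers the whole box,
    which serves as the brute-force reference for the listed evaluation.
    """
    arr = _Arrays(system, ff, cutoff)
    box = arr.effective_box(system)
    pos = np.ascontiguousarray(system.positions, dtype=float)
    d = pos - pos.mean(axis=0)
    span = 2.0 * float(np.linalg.norm(d, axis=1).max()) + 1.0
    rlist = span if all_pairs else cutoff + neighbor_skin
    pairs, count = _neighbor_pairs(arr, pos, box, rlist)
    _check_overlap(pos, box, pairs, count)
    forces, energies, _ = _evaluate(arr, pos, box, pairs, count, cutoff)
    return forces, energies


def _check_overlap(pos, box, pairs, count):
    for p in range(count):
        i, j = pairs[p]
        d = pos[i] - pos[j]
        d -= box * np.round(d / box)
        if float(d @ d) < 1e-12:
            raise SimulationError(f"overlapping particles {i} and {j}")


def minimize_energy(system: CGSystem, ff: ForceField, n_steps: int = 200,
                    max_displacement: float = 0.02, cutoff: float = 1.2,
                    neighbor_skin: float = 0.3) -> float:
    """Adaptive steepest-descent relaxation of bad initial contacts.

    Freshly assembled systems carry lattice-contact strain that would
    otherwise appear as a temperature spike in the first picoseconds of
    dynamics.  Displacements are capped at ``max_displacement`` nm per
    step; the step size adapts to the energy response.  Returns the
    final potential energy (kJ/mol); ``system.positions`` are updated
    in place.
    """
    arr = _Arrays(system, ff, cutoff)
    box = arr.effective_box(system)
    pos = np.ascontiguousarray(system.positions, dtype=float).copy()
    rlist = cutoff + neighbor_skin
    pairs, count = _neighbor_pairs(arr, pos, box, rlist)
    ref = pos.copy()
    forces, energies, _ = _evaluate(arr, pos, box, pairs, count, cutoff)
    e = energies["potential"]
    alpha = 1e-4
    for _ in range(n_steps):
        step = alpha * forces
        norm = np.linalg.norm(step, axis=1)
        big = norm > max_displacement
        if big.any():
            step[big] *= (max_displacement / norm[big])[:, None]
        trial = pos + step
        if K.max_displacement(trial, ref, box) > 0.5 * neighbor_skin:
            pairs, count = _neighbor_pairs(arr, trial, box, rlist)
            ref = trial.copy()
        f_new, en, _ = _evaluate(arr, trial, box, pairs, count, cutoff)
        if en["potential"] < e:
            pos, forces, e = trial, f_new, en["potential"]
            alpha *= 1.2
        else:
            alpha *= 0.5
            if alpha < 1e-10:
                break
    system.positions = pos
    return float(e)


def _init_velocities(masses, temperature, rng):
    n = len(masses)
    v = rng.standard_normal((n, 3)) * np.sqrt(KB * temperature / masses)[:, None]
    p = (masses[:, None] * v).sum(axis=0) / masses.sum()
    v -= p  # remove centre-of-mass drift
    return v


def _kinetic(masses, vel):
    return 0.5 * float((masses[:, None] * vel * vel).sum())


def run_md(system: CGSystem, ff: ForceField, config: SimulationConfig,
           pull: Optional[PullSpec] = None,
           environment_mask: Optional[np.ndarray] = None) -> Trajectory:
    """Integrate the system and return sampled frames.

    Velocities are drawn from the Maxwell-Boltzmann distribution at the
    target temperature (seeded), unless the system already carries
    velocities.  With a :class:`PullSpec`, a phantom particle moves at
    constant velocity along the pull axis and drags the target beads
    through a harmonic spring; each output frame then records the
    pull coordinate (z distance to the membrane midplane estimated from
    the mean of all particles' z) and, if ``environment_mask`` is given,
    the probe-environment nonbonded energy.
    """
    config.validate(system.box, system.periodic)
    cutoff = config.cutoff
    arr = _Arrays(system, ff, cutoff)
    pos = np.ascontiguousarray(system.positions, dtype=float).copy()
    boxv = system.box.astype(float).copy()
    masses = arr.masses
    rng = np.random.default_rng(config.seed)
    if system.velocities is not None:
        vel = system.velocities.copy()
    else:
        vel = _init_velocities(masses, config.temperature, rng)
    ndof = max(3 * len(masses) - 3, 3)

    axis = None
    phantom = None
    if pull is not None:
        axis = np.asarray(pull.axis, dtype=float)
        axis /= np.linalg.norm(axis)
        tsel = np.asarray(pull.targets, dtype=np.int64)
        phantom = (np.asarray(pull.start, dtype=float) if pull.start is not None
                   else pos[tsel].mean(axis=0).copy())

    box = arr.effective_box(system)
    rlist = cutoff + config.neighbor_skin
    pairs, count = _neighbor_pairs(arr, pos, box, rlist)
    ref_pos = pos.copy()
    forces, energies, virial = _evaluate(arr, pos, box, pairs, count, cutoff)

    frames: Trajectory = []
    semi = config.barostat_mode == "semiisotropic"
    for step in range(config.n_steps + 1):
        # synchronise the half-step leapfrog velocities with the positions
        # for reporting (v(t) = v(t-dt/2) + a(t) dt/2)
        v_sync = vel + 0.5 * forces / masses[:, None] * config.dt
        ke = _kinetic(masses, v_sync)
        T_inst = 2.0 * ke / (ndof * KB)
        if step % config.output_stride == 0 or step == config.n_steps:
            e = dict(energies)
            e["kinetic"] = ke
            e["total"] = ke + e["potential"]
            rec = None
            if pull is not None:
                midplane = float(pos[environment_mask, 2].mean()) \
                    if environment_mask is not None else float(pos[:, 2].mean())
                depth = float(pos[tsel, 2].mean() - midplane)
                rec = {"depth": depth,
                       "phantom": float(phantom @ axis)}
                if environment_mask is not None and len(tsel) == 1:
                    rec["probe_env_energy"] = float(K.probe_environment_energy(
                        pos, box, int(tsel[0]), environment_mask, arr.tidx,
                        arr.style, arr.eps, arr.sig, arr.shift, arr.mu,
                        arr.kappa, arr.eta, cutoff))
            frames.append(Frame(step, step * config.dt, pos.copy(),
                                boxv.copy(), T_inst, e, rec))
        if step == config.n_steps:
            break

        f = forces
        if pull is not None:
            ext = pull.spring_k * (phantom - pos[tsel].mean(axis=0)) / len(tsel)
            f = forces.copy()
            f[tsel] += ext

        # leapfrog velocity and position update
        vel += f / masses[:, None] * config.dt
        if config.tau_T is not None:
            ke = _kinetic(masses, vel)
            T_now = 2.0 * ke / (ndof * KB)
            lam = math.sqrt(max(0.0, 1.0 + config.dt / config.tau_T
                                * (config.temperature / max(T_now, 1e-10) - 1.0)))
            vel *= lam
        if np.max(np.abs(vel)) > 100.0:
            worst = int(np.argmax(np.abs(vel).max(axis=1)))
            raise SimulationError(
                f"velocity divergence at step {step} (particle {worst}); "
                f"T_inst={T_inst:.1f} K")
        pos += vel * config.dt
        if pull is not None:
            phantom = phantom + pull.velocity * config.dt * axis
            if np.any(phantom < -boxv) or np.any(phantom > 2.0 * boxv):
                raise SimulationError(
                    f"phantom particle left the box at step {step}")

        # Berendsen barostat: scale box and coordinates toward target P
        if config.tau_P is not None and any(system.periodic):
            vol = float(np.prod(boxv))
            ke_ax = 0.5 * (masses[:, None] * vel * vel).sum(axis=0)
            p_ax = (2.0 * ke_ax + virial) / vol / ATM  # atm
            if semi:
                p_xy = 0.5 * (p_ax[0] + p_ax[1])
                scale = np.array([p_xy, p_xy, p_ax[2]])
            else:
                scale = np.full(3, p_ax.mean())
            mu_ax = np.cbrt(1.0 - config.compressibility * config.dt
                            / config.tau_P * (config.pressure - scale))
            mu_ax = np.clip(mu_ax, 0.98, 1.02)
            for axn in range(3):
                if not system.periodic[axn]:
                    mu_ax[axn] = 1.0
            boxv *= mu_ax
            pos *= mu_ax
            box = boxv.copy()
            for axn in range(3):
                if not system.periodic[axn]:
                    box[axn] = 1e6

        if K.max_displacement(pos, ref_pos, box) > 0.5 * config.neighbor_skin:
            pairs, count = _neighbor_pairs(arr, pos, box, rlist)
            ref_pos = pos.copy()
        forces, energies, virial = _evaluate(arr, pos, box, pairs, count, cutoff)

    system.positions = pos
    system.velocities = vel
    system.box = boxv
    return frames


def steered_pull(system: CGSystem, ff: ForceField, config: SimulationConfig,
                 pull: PullSpec):
    """Drag the pull targets through the box; return the pull profile.

    The profile is a dict of arrays: ``depth`` (nm, z of the probe
    relative to the membrane midplane), ``energy`` (kJ/mol, probe to
    lipid+water nonbonded energy) and ``time`` (ps).  The membrane
    midplane is the instantaneous mean z of all lipid beads.
    """
    env_mask = np.array([r in ("lipid-head", "lipid-tail", "water")
                         for r in system.roles])
    lipid_mask = np.array([r in ("lipid-head", "lipid-tail")
                           for r in system.roles])
    if not lipid_mask.any():
        raise SimulationError("steered pull requires a membrane system")
    frames = run_md(system, ff, config, pull=pull,
                    environment_mask=env_mask)
    # recompute depth against the lipid midplane for the profile
    depth = []
    energy = []
    time = []
    tsel = np.asarray(pull.targets, dtype=np.int64)
    for fr in frames:
        if fr.pull is None or "probe_env_energy" not in fr.pull:
            continue
        mid = float(fr.positions[lipid_mask, 2].mean())
        depth.append(float(fr.positions[tsel, 2].mean() - mid))
        energy.append(fr.pull["probe_env_energy"])
        time.append(fr.time)
    return {"time": np.array(time), "depth": np.array(depth),
            "energy": np.array(energy)}
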