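"""Coarse-grained force field: particle types and potential-energy terms.

The model maps each amino acid onto two interaction sites (backbone bead
at the C-alpha position, sidechain bead along the C-alpha/C-beta vector)
and describes lipids and water with the head/tail/water bead types of a
companion bilayer model.  The total potential is a sum of five terms:
plain Lennard-Jones pairs, hydrogen-bond-augmented Lennard-Jones pairs
between backbone beads, harmonic bonds, harmonic angles (lipid tails)
and double-well ("double angle") backbone angles.

Two terms are specific to this model:

* the *double angle potential*, a quartic with minima at two equilibrium
  angles (helix near 91 degrees, coil near 123 degrees) separated by a
  finite barrier, so a single backbone bead type can populate both
  secondary-structure basins;
* the *LJHB potential*, a Lennard-Jones term plus an inverted Gaussian
  well at the backbone-backbone hydrogen-bond distance (0.61 nm), which
  stabilises alpha-helices without torsion terms.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Optional, Tuple

from .units import RMIN_FACTOR, deg2rad

__all__ = [
    "ParticleType",
    "BondParams",
    "HarmonicAngleParams",
    "DoubleAngleParams",
    "PairParams",
    "ForceField",
    "solve_xi",
    "double_angle_energy_force",
    "pair_energy_force",
    "load_forcefield",
    "default_forcefield",
    "ForceFieldError",
]

#: Interaction groups recognised by the pair-energy tables.
GROUPS = ("polar", "apolar", "aromatic", "neutral", "lipid-head", "lipid-tail", "water")

#: Backbone bead codes (mass variants; BG carries no sidechain bead).
BACKBONE_TYPES = ("BB", "BP", "BG")

#: Sidechain interaction group per one-letter residue code.
RESIDUE_GROUP = {
    "R": "polar", "D": "polar", "E": "polar", "K": "polar",
    "N": "polar", "Q": "polar", "P": "polar",
    "A": "apolar", "I": "apolar", "M": "apolar",
    "L": "apolar", "F": "apolar", "V": "apolar",
    "H": "aromatic", "W": "aromatic", "Y": "aromatic",
    "C": "neutral", "T": "neutral", "S": "neutral",
}


class ForceFieldError(ValueError):
    """Raised for invalid or inconsistent force-field definitions."""


@dataclass(frozen=True)
class ParticleType:
    """A named CG species: backbone, sidechain, lipid head/tail or water."""

    name: str
    mass: float  # amu
    radius: float  # nm, van der Waals radius of the bead
    group: str

    def __post_init__(self):
        if self.mass <= 0:
            raise ForceFieldError(f"{self.name}: mass must be positive")
        if self.radius <= 0:
            raise ForceFieldError(f"{self.name}: radius must be positive")
        if self.group not in GROUPS:
            raise ForceFieldError(f"{self.name}: unknown group {self.group!r}")


@dataclass(frozen=True)
class BondParams:
    r0: float  # nm
    k: float  # kJ/mol/nm^2

    def __post_init__(self):
        if self.r0 <= 0 or self.k <= 0:
            raise ForceFieldError(f"invalid bond parameters r0={self.r0}, k={self.k}")


@dataclass(frozen=True)
class HarmonicAngleParams:
    theta0: float  # radians
    k_theta: float  # kJ/mol/rad^2

    def __post_init__(self):
        if not 0 < self.theta0 <= math.pi + 1e-12:
            raise ForceFieldError(f"theta0={self.theta0} outside (0, pi]")


def _g(theta, theta1, theta2, xi):
    """Quartic core of the double angle potential (stationary at theta1, theta2, xi)."""
    return (
        0.25 * theta ** 4
        - (theta1 + theta2 + xi) * theta ** 3 / 3.0
        + 0.5 * (theta1 * theta2 + theta1 * xi + theta2 * xi) * theta ** 2
        - theta1 * theta2 * xi * theta
    )


def _coefficients(theta1, xi, V1, Vbar, theta2):
    """A and D from the well/barrier constraints V(theta1)=V1, V(xi)=Vbar."""
    g1 = _g(theta1, theta1, theta2, xi)
    gx = _g(xi, theta1, theta2, xi)
    A = (Vbar - V1) / (gx - g1)
    D = (g1 * Vbar - gx * V1) / (g1 - gx)
    return A, D


def solve_xi(theta1: float, theta2: float, V1: float, V2: float, Vbar: float,
             tol: float = None, max_iter: int = 100) -> float:
    """Locate the barrier angle xi of the double angle potential.

    The quartic is fixed by five parameters: the two equilibrium angles,
    their well energies and the barrier energy.  The barrier *position*
    xi is not given; it is the root in (theta1, theta2) of the residual
    V(theta2; xi) - V2, where A and D are re-derived from V(theta1)=V1
    and V(xi)=Vbar for each trial xi.  Newton-Raphson from the midpoint,
    with a bisection fallback if an iterate leaves the bracket.

    All angles in radians, energies in kJ/mol.
    """
    if not theta1 < theta2:
        raise ForceFieldError("solve_xi requires theta1 < theta2")
    if Vbar <= max(V1, V2):
        raise ForceFieldError(
            f"barrier energy {Vbar} must exceed both well energies ({V1}, {V2})")
    # the residual is evaluated through a large cancellation, so its
    # attainable floor scales with the energy magnitudes
    scale = max(1.0, abs(V1), abs(V2), abs(Vbar))
    if tol is None:
        tol = 1e-12 * scale

    def residual(xi):
        A, D = _coefficients(theta1, xi, V1, Vbar, theta2)
        return A * _g(theta2, theta1, theta2, xi) + D - V2

    # keep strictly inside (theta1, theta2): the A/D construction is
    # singular at the endpoints
    pad = 1e-4 * (theta2 - theta1)
    lo, hi = theta1 + pad, theta2 - pad
    f_lo = residual(lo)
    xi = 0.5 * (theta1 + theta2)
    h = 1e-8 * (theta2 - theta1)
    best_xi, best_f = xi, float("inf")
    stagnant = 0
    for _ in range(max_iter):
        f = residual(xi)
        if abs(f) < tol:
            return xi
        if abs(f) < best_f:
            best_xi, best_f = xi, abs(f)
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= 8:  # roundoff floor reached
                break
        # maintain the bracket for the bisection fallback
        if f_lo * f < 0:
            hi = xi
        else:
            lo, f_lo = xi, f
        df = (residual(xi + h) - residual(xi - h)) / (2 * h)
        step_ok = df != 0
        if step_ok:
            xi_new = xi - f / df
            step_ok = lo < xi_new < hi
        xi = xi_new if step_ok else 0.5 * (lo + hi)
    if best_f < 1e-10 * scale:
        return best_xi
    raise ForceFieldError(
        f"xi solve did not converge after {max_iter} iterations; "
        f"residual={best_f:.3e}")


@dataclass(frozen=True)
class DoubleAngleParams:
    """Double-well angle potential V(theta) = A*g(theta) + D.

    Constructed from (theta1, theta2, V1, V2, Vbar); the barrier angle
    xi and the coefficients A, D are derived at construction so that
    V(theta1)=V1, V(theta2)=V2 and V(xi)=Vbar, with dV/dtheta vanishing
    at all three angles.
    """

    theta1: float
    theta2: float
    V1: float
    V2: float
    Vbar: float
    xi: float = field(init=False)
    A: float = field(init=False)
    D: float = field(init=False)

    def __post_init__(self):
        xi = solve_xi(self.theta1, self.theta2, self.V1, self.V2, self.Vbar)
        A, D = _coefficients(self.theta1, xi, self.V1, self.Vbar, self.theta2)
        object.__setattr__(self, "xi", xi)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "D", D)

    def energy(self, theta: float) -> float:
        return self.A * _g(theta, self.theta1, self.theta2, self.xi) + self.D

    def denergy(self, theta: float) -> float:
        """dV/dtheta = A (theta-theta1)(theta-theta2)(theta-xi)."""
        return self.A * (theta - self.theta1) * (theta - self.theta2) * (theta - self.xi)


def double_angle_energy_force(theta: float, params: DoubleAngleParams):
    """Energy (kJ/mol) and dV/dtheta (kJ/mol/rad) of the double angle term."""
    if not 0.0 < theta < math.pi:
        raise ValueError(f"angle {theta} rad outside (0, pi)")
    return params.energy(theta), params.denergy(theta)


@dataclass(frozen=True)
class PairParams:
    """Nonbonded pair interaction: plain LJ, repulsive-only WCA, or LJHB."""

    style: str  # "LJ" | "WCA" | "LJHB"
    epsilon: float  # kJ/mol
    sigma: float  # nm
    mu: float = 0.0  # nm, H-bond minimum location (LJHB)
    kappa: float = 0.0  # nm, H-bond well width (LJHB)
    eta: float = 0.0  # kJ/mol, H-bond well depth (LJHB)

    def __post_init__(self):
        if self.style not in ("LJ", "WCA", "LJHB"):
            raise ForceFieldError(f"unknown pair style {self.style!r}")
        if self.epsilon < 0 or self.sigma <= 0:
            raise ForceFieldError("epsilon must be >= 0 and sigma > 0")
        if self.style == "LJHB":
            if self.mu <= RMIN_FACTOR * self.sigma:
                raise ForceFieldError(
                    "LJHB H-bond minimum mu must lie outside the LJ minimum")
            if self.kappa <= 0 or self.eta <= 0:
                raise ForceFieldError("LJHB requires kappa > 0 and eta > 0")


def pair_energy_force(r: float, params: PairParams):
    """Energy (kJ/mol) and radial force -dV/dr (kJ/mol/nm) at separation r (nm)."""
    if r <= 0:
        raise ValueError("pair separation must be positive")
    eps, sig = params.epsilon, params.sigma
    sr6 = (sig / r) ** 6
    e_lj = 4.0 * eps * (sr6 * sr6 - sr6)
    f_lj = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r  # -dV/dr
    if params.style == "LJ":
        return e_lj, f_lj
    if params.style == "WCA":
        if r >= RMIN_FACTOR * sig:
            return 0.0, 0.0
        return e_lj + eps, f_lj
    # LJHB: LJ plus inverted Gaussian H-bond well
    dr = r - params.mu
    gauss = params.eta * math.exp(-0.5 * dr * dr / (params.kappa ** 2))
    e = e_lj - gauss
    f = f_lj - gauss * dr / (params.kappa ** 2)
    return e, f


def _pair_key(a: str, b: str) -> Tuple[str, str]:
    return (a, b) if a <= b else (b, a)


class ForceField:
    """Complete parameter set: particle types, bonded tables, pair rules.

    Pair interactions are resolved per unordered type pair: the style
    and well depth come from an explicit type-pair override or from the
    interaction-group matrix, while sigma follows the contact rule
    2^(1/6) sigma_ij = radius_i + radius_j (LJ minimum at the contact
    distance of the two van der Waals spheres) unless overridden.
    Backbone-backbone pairs always carry the LJHB hydrogen-bond well.
    """

    def __init__(self, particle_types, bond_table, harmonic_angles,
                 double_angles, group_eps, type_overrides, ljhb):
        self.particle_types: Dict[str, ParticleType] = dict(particle_types)
        self.bond_table: Dict[Tuple[str, str], BondParams] = {
            _pair_key(*k): v for k, v in bond_table.items()}
        self.harmonic_angles: Dict[str, HarmonicAngleParams] = dict(harmonic_angles)
        self.double_angles: Dict[str, DoubleAngleParams] = dict(double_angles)
        self.group_eps: Dict[Tuple[str, str], object] = {
            _pair_key(*k): v for k, v in group_eps.items()}
        self.type_overrides: Dict[Tuple[str, str], object] = {
            _pair_key(*k): v for k, v in type_overrides.items()}
        self.ljhb_mu, self.ljhb_kappa, self.ljhb_eta = ljhb
        self._pair_cache: Dict[Tuple[str, str], PairParams] = {}
        self.validate()

    # -- lookups ---------------------------------------------------------

    def sigma(self, a: str, b: str) -> float:
        ra = self.particle_types[a].radius
        rb = self.particle_types[b].radius
        return (ra + rb) / RMIN_FACTOR

    def bond_params(self, a: str, b: str) -> BondParams:
        try:
            return self.bond_table[_pair_key(a, b)]
        except KeyError:
            raise ForceFieldError(f"no bond parameters for {a}-{b}") from None

    def _resolve_eps(self, a: str, b: str):
        """Well depth (or 'wca') for a type pair, override > group > geometric mean."""
        key = _pair_key(a, b)
        if key in self.type_overrides:
            return self.type_overrides[key]
        ga = self.particle_types[a].group
        gb = self.particle_types[b].group
        gkey = _pair_key(ga, gb)
        if gkey in self.group_eps:
            return self.group_eps[gkey]
        # combining rule: geometric mean of the two self-group energies
        ea = self.group_eps.get((ga, ga))
        eb = self.group_eps.get((gb, gb))
        if isinstance(ea, (int, float)) and isinstance(eb, (int, float)):
            return math.sqrt(ea * eb)
        raise ForceFieldError(f"no pair energy for {a}-{b} (groups {ga}-{gb})")

    def pair_params(self, a: str, b: str) -> PairParams:
        key = _pair_key(a, b)
        if key in self._pair_cache:
            return self._pair_cache[key]
        eps = self._resolve_eps(a, b)
        sig = self.sigma(a, b)
        if a in BACKBONE_TYPES and b in BACKBONE_TYPES:
            if eps == "wca":
                raise ForceFieldError("backbone pairs must be attractive (LJHB)")
            p = PairParams("LJHB", float(eps), sig, mu=self.ljhb_mu,
                           kappa=self.ljhb_kappa, eta=self.ljhb_eta)
        elif eps == "wca":
            p = PairParams("WCA", 1.0, sig)
        else:
            p = PairParams("LJ", float(eps), sig)
        self._pair_cache[key] = p
        return p

    def backbone_type(self, letter: str) -> str:
        return {"G": "BG", "P": "BP"}.get(letter, "BB")

    def sidechain_type(self, letter: str) -> Optional[str]:
        if letter == "G":
            return None
        name = "S" + letter
        if name not in self.particle_types:
            raise ForceFieldError(f"unknown residue code {letter!r}")
        return name

    # -- validation ------------------------------------------------------

    def validate(self):
        problems = []
        for name in BACKBONE_TYPES:
            if name not in self.particle_types:
                problems.append(f"missing backbone type {name}")
        for key in self.type_overrides:
            for t in key:
                if t not in self.particle_types:
                    problems.append(f"pair override references unknown type {t}")
        for key in self.group_eps:
            for g in key:
                if g not in GROUPS:
                    problems.append(f"pair table references unknown group {g}")
        if "backbone" not in self.double_angles:
            problems.append("missing 'backbone' double angle definition")
        if "backbone-sidechain" not in self.double_angles:
            problems.append("missing 'backbone-sidechain' double angle definition")
        if problems:
            raise ForceFieldError("; ".join(problems))
        # every type pair must resolve
        names = sorted(self.particle_types)
        for i, a in enumerate(names):
            for b in names[i:]:
                self.pair_params(a, b)


def _parse_angle_table(tab) -> DoubleAngleParams:
    return DoubleAngleParams(
        theta1=deg2rad(tab["theta1"]), theta2=deg2rad(tab["theta2"]),
        V1=tab["V1"], V2=tab["V2"], Vbar=tab["Vbar"])


def load_forcefield(path) -> ForceField:
    """Read a force-field definition from a TOML file.

    Sections: ``[types]`` (mass amu, radius nm, group), ``[bonds]``
    ("A-B" -> r0 nm, k kJ/mol/nm^2), ``[angles.harmonic]`` and
    ``[angles.double]`` (degrees, kJ/mol), ``[pairs]`` with group matrix,
    per-type overrides and the LJHB block.  Angles are given in degrees
    and converted on load.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    if not raw:
        raise ForceFieldError(f"{path}: empty force-field file")
    for sec in ("types", "bonds", "angles", "pairs"):
        if sec not in raw:
            raise ForceFieldError(f"{path}: missing [{sec}] section")

    types = {}
    for name, t in raw["types"].items():
        types[name] = ParticleType(name, t["mass"], t["radius"], t["group"])

    bonds = {}
    for key, b in raw["bonds"].items():
        a, _, c = key.partition("-")
        if not c:
            raise ForceFieldError(f"bad bond key {key!r} (expected 'A-B')")
        for t in (a, c):
            if t not in types:
                raise ForceFieldError(f"bond {key}: unknown type {t}")
        bonds[(a, c)] = BondParams(b["r0"], b["k"])

    harm = {}
    for name, h in raw["angles"].get("harmonic", {}).items():
        harm[name] = HarmonicAngleParams(deg2rad(h["theta0"]), h["k"])
    dbl = {}
    for name, d in raw["angles"].get("double", {}).items():
        dbl[name] = _parse_angle_table(d)

    pairs = raw["pairs"]
    group_eps = {}
    for key, v in pairs.get("groups", {}).items():
        a, _, c = key.partition(":")
        group_eps[(a, c)] = v if v == "wca" else float(v)
    overrides = {}
    for key, v in pairs.get("types", {}).items():
        a, _, c = key.partition(":")
        for t in (a, c):
            if t not in types:
                raise ForceFieldError(f"pair override {key}: unknown type {t}")
        overrides[(a, c)] = v if v == "wca" else float(v)
    lj = pairs.get("ljhb", {})
    ljhb = (lj.get("mu", 0.61), lj.get("kappa", 0.015), lj.get("eta", 15.0))

    return ForceField(types, bonds, harm, dbl, group_eps, overrides, ljhb)


def default_forcefield() -> ForceField:
    """The force field shipped with the package (see data/forcefield.toml)."""
    ref = resources.files("cgmemsim.data") / "forcefield.toml"
    with resources.as_file(ref) as p:
        return load_forcefield(p)
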