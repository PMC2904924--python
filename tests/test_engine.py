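"""MD engine: force correctness, integrator conservation laws,
thermostat behaviour, reproducibility and steered pulls."""

import numpy as np
import pytest

from cgmemsim.builder import (
    CGSystem,
    PeptideSpec,
    build_membrane,
    build_walp,
    solvate_and_embed,
    walp_sequence,
)
from cgmemsim.engine import (
    PullSpec,
    SimulationConfig,
    SimulationError,
    compute_forces,
    run_md,
    steered_pull,
)
from cgmemsim.forcefield import BondParams


def water_cluster(rng, n=27, spacing=0.45):
    """Small LJ water cluster in a big non-periodic box."""
    g = int(round(n ** (1 / 3)))
    pts = np.array([[i, j, k] for i in range(g) for j in range(g)
                    for k in range(g)], dtype=float) * spacing
    pts += rng.normal(0, 0.01, pts.shape)
    return CGSystem(
        type_names=["W"] * len(pts),
        positions=pts + 5.0,
        molecule_ids=list(range(len(pts))),
        residue_indices=[0] * len(pts),
        roles=["water"] * len(pts),
        box=np.full(3, 20.0),
    )


def random_peptide_system(ff, rng):
    """20-bead disordered peptide-like system exercising every term."""
    s = build_walp(PeptideSpec(walp_sequence(12)), ff)
    s.positions = s.positions + rng.normal(0, 0.03, s.positions.shape)
    return s


class TestForces:
    def test_bonded_pair_at_equilibrium_has_zero_force(self, ff):
        s = CGSystem(
            type_names=["BB", "BB"],
            positions=np.array([[0.0, 0, 0], [0.384, 0, 0]]),
            molecule_ids=[0, 0], residue_indices=[0, 1],
            roles=["backbone", "backbone"],
            bonds=[(0, 1, BondParams(0.384, 5000.0))],
        )
        f, e = compute_forces(s, ff)
        assert e["bond"] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(f, 0.0, atol=1e-9)

    def test_forces_match_finite_difference(self, ff, rng):
        s = random_peptide_system(ff, rng)
        f, e0 = compute_forces(s, ff, all_pairs=True)
        h = 1e-5
        p0 = s.positions.copy()
        for _ in range(12):
            i = int(rng.integers(s.n_particles))
            ax = int(rng.integers(3))
            s.positions = p0.copy()
            s.positions[i, ax] += h
            _, ep = compute_forces(s, ff, all_pairs=True)
            s.positions = p0.copy()
            s.positions[i, ax] -= h
            _, em = compute_forces(s, ff, all_pairs=True)
            fd = -(ep["potential"] - em["potential"]) / (2 * h)
            assert f[i, ax] == pytest.approx(fd, rel=1e-5, abs=1e-4)
        s.positions = p0

    def test_neighbor_list_matches_all_pairs(self, ff, rng):
        s = random_peptide_system(ff, rng)
        s.box = np.full(3, 6.0)
        s.periodic = (True, True, True)
        _, e_list = compute_forces(s, ff, all_pairs=False)
        _, e_all = compute_forces(s, ff, all_pairs=True)
        for k in e_all:
            assert e_list[k] == pytest.approx(e_all[k], abs=1e-10)

    def test_excluded_pairs_contribute_nothing(self, ff):
        """Two bonded beads far apart: huge LJ would apply if not excluded."""
        s = CGSystem(
            type_names=["BB", "BB"],
            positions=np.array([[0.0, 0, 0], [0.05, 0, 0]]),
            molecule_ids=[0, 0], residue_indices=[0, 1],
            roles=["backbone", "backbone"],
            bonds=[(0, 1, BondParams(0.05, 1.0))],
        )
        _, e = compute_forces(s, ff)
        assert e["lj"] == 0.0 and e["ljhb"] == 0.0

    def test_overlapping_particles_are_fatal(self, ff):
        s = CGSystem(
            type_names=["W", "W"],
            positions=np.array([[1.0, 1, 1], [1.0, 1, 1]]),
            molecule_ids=[0, 1], residue_indices=[0, 0],
            roles=["water", "water"],
        )
        with pytest.raises(SimulationError, match="overlap"):
            compute_forces(s, ff)


class TestIntegrator:
    def test_free_particle_moves_in_a_straight_line(self, ff):
        s = CGSystem(
            type_names=["W"], positions=np.array([[5.0, 5.0, 5.0]]),
            molecule_ids=[0], residue_indices=[0], roles=["water"],
            box=np.full(3, 100.0),
            velocities=np.array([[0.1, 0.05, -0.02]]),
        )
        cfg = SimulationConfig(n_steps=500, tau_T=None, output_stride=100)
        frames = run_md(s, ff, cfg)
        v = np.array([0.1, 0.05, -0.02])
        expect = np.array([5.0, 5.0, 5.0]) + v * frames[-1].time
        np.testing.assert_allclose(frames[-1].positions[0], expect, atol=1e-10)
        assert frames[-1].energies["kinetic"] == pytest.approx(
            frames[0].energies["kinetic"], rel=1e-12)

    def test_nve_energy_drift_below_tenth_percent(self, ff, rng):
        s = water_cluster(rng)
        cfg = SimulationConfig(n_steps=834, tau_T=None, seed=3,  # ~10 ps
                               temperature=150.0, output_stride=50)
        s.velocities = None
        # gentle velocities from the seeded Maxwell-Boltzmann draw
        frames = run_md(s, ff, cfg)
        e = np.array([f.energies["total"] for f in frames])
        assert np.max(np.abs(e - e[0])) / abs(e[0]) < 1e-3

    def test_linear_momentum_conserved_without_coupling(self, ff, rng):
        s = water_cluster(rng)
        cfg = SimulationConfig(n_steps=300, tau_T=None, seed=5,
                               temperature=150.0, output_stride=300)
        run_md(s, ff, cfg)
        m = s.masses(ff)
        p = (m[:, None] * s.velocities).sum(axis=0)
        assert np.all(np.abs(p) < 1e-8)

    def test_berendsen_drives_temperature_to_target(self, ff, rng):
        s = water_cluster(rng, n=125, spacing=0.45)
        cfg = SimulationConfig(n_steps=200, tau_T=0.1, temperature=324.0,
                               seed=7, output_stride=20)
        s.velocities = None
        frames = run_md(s, ff, cfg)
        # after 10 tau_T the instantaneous T sits near the target
        late = [f.temperature for f in frames if f.time >= 1.0]
        assert abs(np.mean(late) - 324.0) / 324.0 < 0.05

    def test_trajectory_is_reproducible_for_fixed_seed(self, ff):
        results = []
        for _ in range(2):
            s = build_walp(PeptideSpec(walp_sequence(12)), ff)
            cfg = SimulationConfig(n_steps=200, seed=42, output_stride=200)
            frames = run_md(s, ff, cfg)
            results.append(frames[-1].positions.copy())
        np.testing.assert_array_equal(results[0], results[1])

    def test_helix_keeps_published_bond_length(self, ff):
        """Short thermal run: mean backbone bond stays at 0.384 nm."""
        s = build_walp(PeptideSpec(walp_sequence(16)), ff)
        cfg = SimulationConfig(n_steps=8000, seed=11, output_stride=500)
        frames = run_md(s, ff, cfg)
        bb = s.backbone_indices()
        late = [np.linalg.norm(f.positions[bb][1:] - f.positions[bb][:-1],
                               axis=1).mean()
                for f in frames if f.time > frames[-1].time / 2]
        assert np.mean(late) == pytest.approx(0.384, abs=0.01)

    def test_divergence_aborts_with_diagnostic(self, ff):
        s = CGSystem(
            type_names=["W", "W"],
            positions=np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 5.03]]),
            molecule_ids=[0, 1], residue_indices=[0, 0],
            roles=["water", "water"],
            box=np.full(3, 20.0),
            velocities=np.zeros((2, 3)),
        )
        cfg = SimulationConfig(n_steps=50, tau_T=None, output_stride=10)
        with pytest.raises(SimulationError, match="velocity divergence"):
            run_md(s, ff, cfg)

    def test_cutoff_must_fit_periodic_box(self, ff):
        s = water_cluster(np.random.default_rng(0))
        s.box = np.full(3, 2.0)
        s.periodic = (True, True, True)
        with pytest.raises(SimulationError, match="half"):
            run_md(s, ff, SimulationConfig(n_steps=1))


class TestSteeredPull:
    def test_spring_at_zero_extension_exerts_no_force(self, ff):
        """With the phantom on top of the probe the pull force vanishes."""
        s = CGSystem(
            type_names=["W"], positions=np.array([[5.0, 5.0, 5.0]]),
            molecule_ids=[0], residue_indices=[0], roles=["water"],
            box=np.full(3, 50.0),
            velocities=np.zeros((1, 3)),
        )
        pull = PullSpec(targets=[0], velocity=1e-12)
        cfg = SimulationConfig(n_steps=10, tau_T=None, output_stride=10)
        frames = run_md(s, ff, cfg, pull=pull)
        np.testing.assert_allclose(frames[-1].positions[0],
                                   [5.0, 5.0, 5.0], atol=1e-9)

    def test_pull_profile_is_recorded_and_probe_follows(self, ff):
        """A short pull drags the probe upward and records (depth, energy)."""
        from cgmemsim.fixtures import FixtureSpec, make_fixture
        system, sidecar = make_fixture(
            FixtureSpec("probe-pull", {"probe": "SL", "area": 9.0}), ff)
        z0 = system.positions[0, 2]
        cfg = SimulationConfig(n_steps=8000, seed=13, output_stride=400)
        profile = steered_pull(system, ff, cfg,
                               PullSpec(targets=[0], velocity=0.01))
        assert len(profile["depth"]) == len(profile["energy"]) > 10
        # 8000 steps x 12 fs x 0.01 nm/ps ~ 1 nm of phantom travel
        assert profile["depth"][-1] > profile["depth"][0] + 0.4

    @pytest.mark.parametrize("probe,region", [("SL", "core"), ("SW", "interface")])
    def test_probe_depth_energy_preference(self, ff, probe, region):
        """Apolar beads favour the membrane core, aromatics the interface.

        The probe-environment nonbonded energy is scanned across the
        depth of a freshly built H4T4T4 bilayer (best lateral placement
        per depth); the minimum falls in the tail region for Leu and in
        the head-group region for Trp.
        """
        from cgmemsim._kernels import probe_environment_energy
        from cgmemsim.builder import build_membrane, solvate_and_embed
        from cgmemsim.engine import _Arrays

        mem = build_membrane("H4T4T4", 9.0, ff)
        sys_ = solvate_and_embed(mem, ff, water_margin=1.2)
        probe_sys = CGSystem(
            type_names=[probe] + sys_.type_names,
            positions=np.vstack([[0.0, 0.0, 0.0], sys_.positions]),
            molecule_ids=[0] + [m + 1 for m in sys_.molecule_ids],
            residue_indices=[0] + sys_.residue_indices,
            roles=["sidechain"] + sys_.roles,
            box=sys_.box.copy(), periodic=sys_.periodic,
        )
        arr = _Arrays(probe_sys, ff, 1.2)
        box = arr.effective_box(probe_sys)
        mask = np.array([r in ("lipid-head", "lipid-tail", "water")
                         for r in probe_sys.roles])
        zs = np.arange(-3.0, 3.01, 0.1)
        offsets = [(dx, dy) for dx in (0.0, 0.2, 0.4) for dy in (0.0, 0.2, 0.4)]
        prof = []
        pos = probe_sys.positions
        for z in zs:
            best = np.inf
            for dx, dy in offsets:
                pos[0] = [2.0 + dx, 2.0 + dy, z]
                e = probe_environment_energy(
                    pos, box, 0, mask, arr.tidx, arr.style, arr.eps, arr.sig,
                    arr.shift, arr.mu, arr.kappa, arr.eta, 1.2)
                best = min(best, e)
            prof.append(best)
        zmin = zs[int(np.argmin(prof))]
        head_lo = 1.52 - 0.2  # tail/head boundary of the built bilayer
        if region == "core":
            assert abs(zmin) < head_lo
        else:
            assert head_lo < abs(zmin) < 2.6

    def test_phantom_leaving_the_box_aborts(self, ff):
        s = CGSystem(
            type_names=["W"], positions=np.array([[1.0, 1.0, 1.0]]),
            molecule_ids=[0], residue_indices=[0], roles=["water"],
            box=np.full(3, 2.0),
            velocities=np.zeros((1, 3)),
        )
        pull = PullSpec(targets=[0], velocity=50.0)
        cfg = SimulationConfig(n_steps=100000, tau_T=None, output_stride=1000,
                               cutoff=0.5, neighbor_skin=0.2)
        with pytest.raises(SimulationError, match="phantom"):
            run_md(s, ff, cfg, pull=pull)
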