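"""Potential-energy terms: double-well angle construction, pair styles,
parameter loading and validation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgmemsim.forcefield import (
    DoubleAngleParams,
    ForceFieldError,
    PairParams,
    ParticleType,
    double_angle_energy_force,
    load_forcefield,
    pair_energy_force,
    solve_xi,
)
from cgmemsim.units import RMIN_FACTOR, deg2rad, rad2deg

BACKBONE = dict(theta1=deg2rad(91.25), theta2=deg2rad(123.25),
                V1=0.0, V2=23.0, Vbar=23.7)


class TestSolveXi:
    def test_symmetric_wells_put_barrier_at_midpoint(self):
        xi = solve_xi(deg2rad(80), deg2rad(120), 0.0, 0.0, 10.0)
        assert rad2deg(xi) == pytest.approx(100.0, abs=1e-8)

    def test_backbone_parameters_give_interior_barrier(self):
        xi = solve_xi(**BACKBONE)
        assert BACKBONE["theta1"] < xi < BACKBONE["theta2"]
        p = DoubleAngleParams(**BACKBONE)
        assert p.energy(p.xi) == pytest.approx(23.7, abs=1e-9)

    def test_matches_brute_force_root_bracketing(self):
        """Dense scan of the V(theta2) residual brackets the same root."""
        t1, t2, v1, v2, vb = (deg2rad(85), deg2rad(130), 1.0, 5.0, 12.0)
        xi = solve_xi(t1, t2, v1, v2, vb)

        def residual(x):
            p = DoubleAngleParams.__new__(DoubleAngleParams)
            from cgmemsim.forcefield import _coefficients, _g
            A, D = _coefficients(t1, x, v1, vb, t2)
            return A * _g(t2, t1, t2, x) + D - v2

        grid = np.linspace(t1 + 1e-4, t2 - 1e-4, 100_000)
        vals = np.array([residual(x) for x in grid])
        sign_change = np.where(np.diff(np.sign(vals)) != 0)[0]
        assert len(sign_change) >= 1
        brackets = grid[sign_change]
        assert np.min(np.abs(brackets - xi)) < 1e-4

    def test_barrier_below_wells_is_rejected(self):
        with pytest.raises(ForceFieldError):
            solve_xi(deg2rad(80), deg2rad(120), 0.0, 10.0, 5.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        t1=st.floats(40, 100), width=st.floats(10, 70),
        v1=st.floats(0, 10), v2=st.floats(0, 10), bump=st.floats(0.5, 30),
    )
    def test_construction_constraints_always_hold(self, t1, width, v1, v2, bump):
        params = DoubleAngleParams(
            theta1=deg2rad(t1), theta2=deg2rad(t1 + width),
            V1=v1, V2=v2, Vbar=max(v1, v2) + bump)
        assert params.theta1 < params.xi < params.theta2
        assert params.energy(params.theta1) == pytest.approx(v1, abs=1e-9)
        assert params.energy(params.theta2) == pytest.approx(v2, abs=1e-9)
        assert params.energy(params.xi) == pytest.approx(params.Vbar, abs=1e-9)
        for theta in (params.theta1, params.theta2, params.xi):
            assert abs(params.denergy(theta)) < 1e-9


class TestDoubleAnglePotential:
    def test_wells_have_stated_energies_and_zero_slope(self):
        p = DoubleAngleParams(**BACKBONE)
        e1, d1 = double_angle_energy_force(p.theta1, p)
        e2, d2 = double_angle_energy_force(p.theta2, p)
        assert e1 == pytest.approx(0.0, abs=1e-9)
        assert e2 == pytest.approx(23.0, abs=1e-9)
        assert abs(d1) < 1e-9 and abs(d2) < 1e-9

    def test_derivative_matches_finite_difference(self, rng):
        p = DoubleAngleParams(**BACKBONE)
        h = 1e-5  # A*g(theta) cancels heavily; smaller h amplifies roundoff
        for theta in rng.uniform(0.3, math.pi - 0.3, 20):
            _, d = double_angle_energy_force(theta, p)
            fd = (p.energy(theta + h) - p.energy(theta - h)) / (2 * h)
            assert d == pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_exactly_three_stationary_points(self):
        p = DoubleAngleParams(**BACKBONE)
        grid = np.linspace(1e-3, math.pi - 1e-3, 200_000)
        dv = p.A * (grid - p.theta1) * (grid - p.theta2) * (grid - p.xi)
        crossings = np.where(np.diff(np.sign(dv)) != 0)[0]
        assert len(crossings) == 3
        stationary = sorted(grid[crossings])
        assert stationary[0] == pytest.approx(p.theta1, abs=1e-4)
        assert stationary[1] == pytest.approx(p.xi, abs=1e-4)
        assert stationary[2] == pytest.approx(p.theta2, abs=1e-4)
        # theta1, theta2 are minima; xi is the maximum
        assert p.energy(p.xi) > max(p.energy(p.theta1), p.energy(p.theta2))

    def test_angle_outside_domain_raises(self):
        p = DoubleAngleParams(**BACKBONE)
        with pytest.raises(ValueError):
            double_angle_energy_force(-0.1, p)
        with pytest.raises(ValueError):
            double_angle_energy_force(math.pi + 0.1, p)


class TestPairPotentials:
    def test_wca_is_zero_beyond_truncation(self):
        p = PairParams("WCA", 1.0, 0.4)
        e, f = pair_energy_force(2 * RMIN_FACTOR * 0.4, p)
        assert e == 0.0 and f == 0.0

    def test_wca_is_nonnegative_and_continuous(self):
        p = PairParams("WCA", 1.3, 0.4)
        rmin = RMIN_FACTOR * 0.4
        for r in np.linspace(0.25, 2 * rmin, 300):
            e, _ = pair_energy_force(r, p)
            assert e >= 0.0
        e_at, _ = pair_energy_force(rmin - 1e-9, p)
        assert e_at == pytest.approx(0.0, abs=1e-6)

    def test_ljhb_well_depth_at_hbond_distance(self, ff):
        """At r = mu the Gaussian contributes its full 15 kJ/mol."""
        p = ff.pair_params("BB", "BB")
        assert p.style == "LJHB"
        assert p.mu == 0.61 and p.eta == 15.0 and p.kappa == 0.015
        lj = PairParams("LJ", p.epsilon, p.sigma)
        e_hb, _ = pair_energy_force(0.61, p)
        e_lj, _ = pair_energy_force(0.61, lj)
        assert e_hb == pytest.approx(e_lj - 15.0, abs=1e-12)

    def test_ljhb_reduces_to_lj_far_from_the_well(self, ff):
        p = ff.pair_params("BB", "BB")
        lj = PairParams("LJ", p.epsilon, p.sigma)
        r = p.mu + 10 * p.kappa
        e_hb, _ = pair_energy_force(r, p)
        e_lj, _ = pair_energy_force(r, lj)
        assert abs(e_hb - e_lj) < 1e-6

    def test_ljhb_converges_to_lj_as_eta_vanishes(self, ff):
        base = ff.pair_params("BB", "BB")
        lj = PairParams("LJ", base.epsilon, base.sigma)
        rs = np.linspace(0.42, 1.2, 50)
        for eta in (1e-3, 1e-6):
            p = PairParams("LJHB", base.epsilon, base.sigma,
                           mu=base.mu, kappa=base.kappa, eta=eta)
            diff = max(abs(pair_energy_force(r, p)[0]
                           - pair_energy_force(r, lj)[0]) for r in rs)
            assert diff <= eta + 1e-12

    def test_forces_match_finite_difference(self, rng):
        params = [
            PairParams("LJ", 1.97, 0.4),
            PairParams("WCA", 1.0, 0.4),
            PairParams("LJHB", 1.97, 0.4, mu=0.61, kappa=0.015, eta=15.0),
        ]
        h = 1e-7
        for p in params:
            for r in rng.uniform(0.3, 1.2, 20):
                e, f = pair_energy_force(r, p)
                fd = -(pair_energy_force(r + h, p)[0]
                       - pair_energy_force(r - h, p)[0]) / (2 * h)
                assert f == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_nonpositive_separation_raises(self):
        with pytest.raises(ValueError):
            pair_energy_force(0.0, PairParams("LJ", 1.0, 0.4))

    def test_ljhb_minimum_must_lie_outside_lj_minimum(self):
        with pytest.raises(ForceFieldError):
            PairParams("LJHB", 1.0, 0.4, mu=0.40, kappa=0.015, eta=15.0)


class TestForceFieldLoading:
    def test_environment_energy_tiers(self, ff):
        # polar sidechains and backbone favour water
        assert ff.pair_params("SR", "W").epsilon == pytest.approx(1.97)
        assert ff.pair_params("BB", "W").epsilon == pytest.approx(1.97)
        # aromatics favour the head-group interface, repulsive elsewhere
        p = ff.pair_params("SW", "H")
        assert p.style == "LJ" and p.epsilon == pytest.approx(1.97)
        assert ff.pair_params("SW", "W").style == "WCA"
        assert ff.pair_params("SW", "T").style == "WCA"
        # apolar residues favour the tails; methionine is the 1.00 exception
        assert ff.pair_params("SL", "T").epsilon == pytest.approx(1.97)
        assert ff.pair_params("SM", "T").epsilon == pytest.approx(1.00)
        assert ff.pair_params("SL", "W").style == "WCA"
        # glycine backbone and phenylalanine head-group exceptions
        assert ff.pair_params("BG", "H").epsilon == pytest.approx(1.00)
        assert ff.pair_params("SF", "H").epsilon == pytest.approx(1.00)
        assert ff.pair_params("BB", "H").epsilon == pytest.approx(0.50)
        # neutral group: 0.50 everywhere in the environment
        for env in ("W", "H", "T"):
            assert ff.pair_params("SS", env).epsilon == pytest.approx(0.50)

    def test_pair_table_is_symmetric(self, ff):
        names = sorted(ff.particle_types)
        for a in names[::3]:
            for b in names[::4]:
                pa, pb = ff.pair_params(a, b), ff.pair_params(b, a)
                assert pa == pb
                for r in (0.4, 0.61, 1.0):
                    assert pair_energy_force(r, pa) == pair_energy_force(r, pb)

    def test_backbone_lj_minimum_at_published_contact(self, ff):
        p = ff.pair_params("BB", "BB")
        assert RMIN_FACTOR * p.sigma == pytest.approx(0.448, abs=1e-3)

    def test_empty_file_is_rejected(self, tmp_path):
        f = tmp_path / "empty.toml"
        f.write_text("")
        with pytest.raises(ForceFieldError):
            load_forcefield(f)

    def test_missing_section_is_rejected(self, tmp_path):
        f = tmp_path / "partial.toml"
        f.write_text('[types]\nBB = { mass = 1.0, radius = 0.2, group = "polar" }\n')
        with pytest.raises(ForceFieldError, match="missing"):
            load_forcefield(f)

    def test_negative_mass_is_rejected(self):
        with pytest.raises(ForceFieldError):
            ParticleType("XX", -1.0, 0.2, "polar")

    def test_every_sidechain_maps_to_one_group(self, ff):
        from cgmemsim.forcefield import RESIDUE_GROUP
        groups = {"polar": "RDEKNQP", "apolar": "AIMLFV",
                  "aromatic": "HWY", "neutral": "CTS"}
        for gname, letters in groups.items():
            for aa in letters:
                assert RESIDUE_GROUP[aa] == gname
                assert ff.particle_types["S" + aa].group == gname
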