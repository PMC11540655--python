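"""Explicit solver: assembly, lumping, time stepping, dynamic relaxation."""

import numpy as np
import pytest

import brachysim as bs
from brachysim.constitutive import Material, MaterialField
from brachysim.errors import DivergenceError
from brachysim.solver import (SimState, internal_forces, lumped_mass,
                              relax_to_equilibrium, stable_timestep, step,
                              total_strain_energy)

RHO = 1000.0  # kg/m^3


class TestInternalForces:
    def test_zero_displacement_gives_zero_forces(self, small_box, small_box_table,
                                                 small_box_field):
        state = SimState.zeros(small_box.n_nodes)
        f = internal_forces(state, small_box_table, small_box_field, small_box)
        assert np.all(f == 0.0)

    def test_rigid_translation_invariance(self, small_box, small_box_table,
                                          small_box_field):
        state = SimState.zeros(small_box.n_nodes)
        state.u += np.array([3.0, -2.0, 0.5])
        f = internal_forces(state, small_box_table, small_box_field, small_box)
        assert np.abs(f).max() <= 1e-10

    def test_virtual_work_matches_energy_finite_difference(
            self, small_box, small_box_table, small_box_field, rng):
        state = SimState.zeros(small_box.n_nodes)
        state.u = rng.normal(0.0, 0.02, (small_box.n_nodes, 3))
        f = internal_forces(state, small_box_table, small_box_field, small_box)
        du = rng.normal(0.0, 1.0, (small_box.n_nodes, 3))
        eps = 1e-6

        def energy(u):
            s = SimState.zeros(small_box.n_nodes)
            s.u = u
            return total_strain_energy(s, small_box_table, small_box_field, small_box)

        fd = (energy(state.u + eps * du) - energy(state.u - eps * du)) / (2 * eps)
        work = float(np.sum(f * du))
        assert abs(work - fd) / abs(fd) <= 1e-5


class TestLumpedMass:
    def test_total_mass_conserved(self, small_box, small_box_table, small_box_field):
        m = lumped_mass(small_box, small_box_table, small_box_field)
        V = np.prod(np.ptp(small_box.node_coords, axis=0))
        assert m.sum() == pytest.approx(RHO * V * 1e-9, rel=1e-10)
        assert np.all(m > 0)

    def test_mass_linear_in_density(self, small_box, small_box_table):
        heavy = Material(8.0, 400.0, density=2000.0)
        light = Material(8.0, 400.0, density=1000.0)
        m2 = lumped_mass(small_box, small_box_table,
                         MaterialField.from_domain(small_box, {0: heavy, 1: heavy}))
        m1 = lumped_mass(small_box, small_box_table,
                         MaterialField.from_domain(small_box, {0: light, 1: light}))
        assert np.allclose(m2, 2.0 * m1)

    def test_interior_masses_match_cell_mass(self, small_box, small_box_table,
                                             small_box_field):
        m = lumped_mass(small_box, small_box_table, small_box_field)
        h = small_box.nodal_spacing
        lo = small_box.node_coords.min(0)
        hi = small_box.node_coords.max(0)
        interior = np.all((small_box.node_coords > lo + h / 2)
                          & (small_box.node_coords < hi - h / 2), axis=1)
        cell = RHO * h**3 * 1e-9
        assert np.abs(m[interior] / cell - 1.0).max() <= 0.01


class TestStableTimestep:
    def test_stiffening_reduces_timestep_by_sqrt_factor(self, small_box,
                                                        small_box_field):
        dt0 = stable_timestep(small_box, small_box_field)
        stiff = small_box_field.copy()
        stiff.stiffen(np.arange(10), 30.0)
        dt1 = stable_timestep(small_box, stiff)
        assert dt1 == pytest.approx(dt0 / np.sqrt(30.0), rel=1e-12)

    def test_halving_spacing_halves_timestep(self, small_box_field, small_box):
        fine = bs.box_domain((20, 20, 20), 1.0)
        field_fine = MaterialField.from_domain(
            fine, {0: Material.from_young_poisson(25.0, 0.49)})
        dt_fine = stable_timestep(fine, field_fine)
        dt = stable_timestep(small_box, small_box_field)
        assert dt_fine == pytest.approx(dt / 2.0, rel=1e-12)

    def test_formula_recomputation(self, small_box, small_box_field):
        c = np.sqrt((small_box_field.kappa_eff + 4 * small_box_field.mu_eff / 3)
                    * 1e3 / small_box_field.rho).max() * 1e3
        expected = 0.5 * small_box.nodal_spacing / c
        dt = stable_timestep(small_box, small_box_field)
        assert dt == pytest.approx(expected, rel=1e-12)
        assert 1e-5 <= dt <= 1e-3  # physically plausible band, logged not tuned


class TestStep:
    def test_quiescent_state_unchanged_by_zero_forces(self):
        state = SimState.zeros(10)
        u0 = state.u.copy()
        step(state, np.zeros((10, 3)), np.ones(10), 1e-4, damping=0.1)
        assert np.array_equal(state.u, u0)

    def test_single_mass_oscillator_period(self):
        # one free node, linear spring force, no damping
        m, k = 1e-6, 2.5  # kg, mN/mm
        omega = np.sqrt(k / m)
        dt = 0.001 * 2 * np.pi / omega  # well below the stability limit
        state = SimState.zeros(1)
        state.u[0, 0] = 1.0
        crossings = []
        prev = state.u[0, 0]
        for i in range(int(3 * 2 * np.pi / omega / dt) + 10):
            f = -k * state.u
            step(state, f, np.array([m]), dt, damping=0.0)
            cur = state.u[0, 0]
            if prev > 0 >= cur:
                frac = prev / (prev - cur)
                crossings.append((i + frac) * dt)
            prev = cur
        assert len(crossings) >= 2
        # consecutive downward zero crossings are one full period apart
        period = crossings[1] - crossings[0]
        assert period == pytest.approx(2 * np.pi / omega, rel=1e-4)

    def test_prescribed_node_snaps_to_target(self):
        state = SimState.zeros(4)
        state.set_prescribed(np.array([2]), np.array([[0.5, 0.0, -0.1]]))
        step(state, np.full((4, 3), 100.0), np.full(4, 1e-6), 1e-5, damping=0.0)
        assert np.allclose(state.u[2], [0.5, 0.0, -0.1])

    def test_nan_forces_raise_divergence_error(self):
        state = SimState.zeros(3)
        f = np.zeros((3, 3))
        f[1, 1] = np.nan
        with pytest.raises(DivergenceError):
            step(state, f, np.ones(3), 1e-4)

    def test_damped_free_vibration_dissipates_energy(self, small_box,
                                                     small_box_table,
                                                     small_box_field, rng):
        masses = lumped_mass(small_box, small_box_table, small_box_field)
        dt = stable_timestep(small_box, small_box_field)
        state = SimState.zeros(small_box.n_nodes)
        state.u = rng.normal(0.0, 0.05, (small_box.n_nodes, 3))

        def total_energy():
            # kg (mm/s)^2 = uJ, matching the kPa mm^3 strain-energy unit
            ke = 0.5 * float(np.sum(masses[:, None] * state.v**2))
            return ke + total_strain_energy(state, small_box_table,
                                            small_box_field, small_box)

        energies = [total_energy()]
        for _ in range(40):
            for _ in range(10):
                f = -internal_forces(state, small_box_table, small_box_field,
                                     small_box)
                step(state, f, masses, dt, damping=500.0)
            energies.append(total_energy())
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-12 + 1e-6 * energies[0])


class TestRelaxation:
    def test_zero_load_converges_immediately_at_zero(self, small_box,
                                                     small_box_table,
                                                     small_box_field):
        state = SimState.zeros(small_box.n_nodes,
                               fixed=small_box.boundary_sets["fixed_external"])
        state, rep = relax_to_equilibrium(state, small_box_table, small_box_field,
                                          small_box, mass_scaling=False)
        assert rep.converged and rep.iterations == 50
        assert np.abs(state.u).max() == 0.0

    def test_trajectories_are_deterministic(self, small_box, small_box_table,
                                            small_box_field):
        def run():
            state = SimState.zeros(small_box.n_nodes)
            bidx = small_box.boundary_sets["fixed_external"]
            z = small_box.node_coords[:, 2]
            top = np.flatnonzero(np.isclose(z, z.max()))
            targ = np.zeros((len(top), 3))
            targ[:, 2] = -0.2
            state.fixed = np.setdiff1d(np.flatnonzero(np.isclose(z, 0)), top)
            state.set_prescribed(top, targ)
            state, _ = relax_to_equilibrium(state, small_box_table, small_box_field,
                                            small_box, max_iter=500,
                                            mass_scaling=False)
            return state.u
        assert np.array_equal(run(), run())
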