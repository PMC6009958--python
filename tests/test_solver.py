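"""Flow solver contracts on small fixtures (full BSG runs live in the
acceptance suite)."""

import numpy as np
import pytest

from crosslimb.rheology import RheologyParams, newtonian
from crosslimb.solver import (GridSpec, BoundaryConditions, IBSolver,
                              FlowState, initial_state, solve_steady,
                              solve_pulsatile, SolverError)
from crosslimb.validation import (channel_fixture, tube_fixture,
                                  plane_poiseuille_case)
from crosslimb.waveforms import Waveform


@pytest.fixture(scope="module")
def small_tube():
    grid, sdf, rheo = tube_fixture(12, 5e-3)
    return grid, sdf, rheo


class TestEquilibrium:
    def test_quiescent_fluid_stays_quiescent(self, small_tube):
        """Zero body force, no inflow: u = 0, p = 0 is an exact fixed
        point of the scheme."""
        grid, sdf, rheo = small_tube
        bc = BoundaryConditions(periodic=(False, False, True))
        solver = IBSolver(grid, sdf, rheo, bc)
        st = initial_state(grid)
        solver.apply_bc(st, 0.0)
        st2 = solver.advance(st, 1e-3)
        assert st2.max_speed() < 1e-14
        assert np.max(np.abs(st2.p)) < 1e-10

    def test_uniform_outlet_pressure_equilibrium(self):
        grid, sdf, rheo = tube_fixture(10, 5e-3, nz=6)
        bc = BoundaryConditions(inlet=Waveform(1.0, 0.0),
                                outlet_pressure=13300.0)
        solver = IBSolver(grid, sdf, rheo, bc)
        st = initial_state(grid)
        solver.apply_bc(st, 0.0)
        st2 = solver.advance(st, 1e-3)
        assert st2.max_speed() < 1e-10
        assert np.allclose(st2.p[solver.fluid], 13300.0, atol=1e-6)


class TestStability:
    def test_cfl_violation_raises(self, small_tube):
        grid, sdf, rheo = small_tube
        bc = BoundaryConditions(body_accel=(0, 0, 1.0),
                                periodic=(False, False, True))
        solver = IBSolver(grid, sdf, rheo, bc)
        st = initial_state(grid)
        st.w[:, :, :] = 0.5  # fast flow
        solver.apply_bc(st, 0.0)
        with pytest.raises(SolverError, match="CFL"):
            solver.advance(st, 1.0)

    def test_divergence_free_after_projection(self):
        grid, sdf, rheo = tube_fixture(10, 5e-3, nz=6)
        bc = BoundaryConditions(inlet=Waveform(1.0, 0.02),
                                outlet_pressure=13300.0)
        solver = IBSolver(grid, sdf, rheo, bc)
        st = initial_state(grid)
        solver.apply_bc(st, 0.0)
        for _ in range(5):
            st = solver.advance(st, solver.cfl_dt(st), check_cfl=False)
        assert solver.last_divergence < 1e-8


class TestSteadySolve:
    def test_newtonian_channel_profile(self):
        res = plane_poiseuille_case(ny=16)
        assert abs(res["centerline_error"]) < 0.02
        assert res["centerline_over_mean"] == pytest.approx(1.5, rel=0.02)

    def test_nonconvergence_raises_with_history(self, small_tube):
        grid, sdf, rheo = small_tube
        bc = BoundaryConditions(body_accel=(0, 0, 0.1),
                                periodic=(False, False, True))
        solver = IBSolver(grid, sdf, rheo, bc)
        from crosslimb.solver import ConvergenceError
        with pytest.raises(ConvergenceError, match="residual"):
            solve_steady(solver, tol=1e-14, max_iter=5)

    def test_mass_conservation_through_tube(self):
        """Inlet flux reappears at the outlet to projection accuracy."""
        grid, sdf, rheo = tube_fixture(10, 5e-3, nz=10)
        rheo = newtonian(5.6e-2)
        bc = BoundaryConditions(inlet=Waveform(1.0, 0.02),
                                outlet_pressure=13300.0)
        solver = IBSolver(grid, sdf, rheo, bc)
        st, _ = solve_steady(solver, tol=1e-6, max_iter=2000, strict=False)
        qin = solver.inlet_flux(st)
        qout = solver.outlet_flux(st)
        assert abs(qout - qin) / qin < 0.005


class TestPulsatile:
    def test_zero_pulsatility_matches_steady(self):
        grid, sdf, rheo = tube_fixture(10, 5e-3, nz=6)
        bc = BoundaryConditions(inlet=Waveform(1.0, 0.02),
                                outlet_pressure=Waveform(1.0, 13300.0))
        solver = IBSolver(grid, sdf, rheo, bc)
        # matched pseudo-step size: the fractional-step fixed point has an
        # O(dt^2) splitting dependence, so compare at the pulsatile dt
        steady, _ = solve_steady(solver, tol=1e-9, max_iter=4000,
                                 strict=False, dt_cap=0.005)
        res = solve_pulsatile(solver, steps_per_cycle=200, n_cycles=2,
                              init=steady)
        final = res.snapshots[-1]
        # agreement is limited by the theta-dependent O(dt^2) splitting
        # term of the fractional-step fixed point
        dv = np.max(np.abs(final.w - steady.w)) / np.max(np.abs(steady.w))
        assert dv < 1e-2
        assert res.periodicity[-1] < 1e-6

    def test_periodicity_diagnostic_decreases(self):
        """Starting from rest, successive cycles converge toward the
        periodic solution on the channel fixture."""
        grid, sdf, rheo = channel_fixture(12)
        import math
        om = 2 * np.pi
        bc = BoundaryConditions(
            body_accel=lambda t: (1e-3 * (1 + math.cos(om * t)), 0, 0),
            periodic=(True, False, True))
        solver = IBSolver(grid, sdf, rheo, bc)
        res = solve_pulsatile(solver, steps_per_cycle=40, n_cycles=4,
                              period=1.0, keep_snapshots=False)
        assert np.all(np.diff(res.periodicity) < 0)

    def test_minimum_cadence_enforced(self, small_tube):
        grid, sdf, rheo = small_tube
        bc = BoundaryConditions(periodic=(False, False, True))
        solver = IBSolver(grid, sdf, rheo, bc)
        with pytest.raises(SolverError, match="steps_per_cycle"):
            solve_pulsatile(solver, steps_per_cycle=10, n_cycles=1)


class TestDeterminism:
    def test_identical_runs_bit_identical(self):
        grid, sdf, rheo = tube_fixture(8, 5e-3, nz=4)
        outs = []
        for _ in range(2):
            bc = BoundaryConditions(body_accel=(0, 0, 0.05),
                                    periodic=(False, False, True))
            solver = IBSolver(grid, sdf, rheo, bc)
            st = initial_state(grid)
            solver.apply_bc(st, 0.0)
            for _ in range(10):
                st = solver.advance(st, 2e-3, check_cfl=False)
            outs.append(st)
        assert np.array_equal(outs[0].w, outs[1].w)
        assert np.array_equal(outs[0].p, outs[1].p)
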