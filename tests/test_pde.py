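"""Wall laws, boundary-layer scale, CFL bookkeeping and solver basics.

The heavier solver-physics checks (wave speed, mass conservation, grid
refinement order, pressure monotonicity) live in the acceptance suite.
"""

import math

import numpy as np
import pytest

from pulmo_uq.constants import PhysicalConstants
from pulmo_uq.exceptions import ConfigurationError, DomainError, SolverError
from pulmo_uq.network import NominalWindkessel, Vessel, VesselNetwork
from pulmo_uq.pde import (
    SimulationGrid,
    WallModel,
    area_from_pressure,
    boundary_layer_thickness,
    check_cfl,
    simulate,
    stable_dt,
    stiffness,
    wall_pressure,
)


class TestStiffness:
    def test_constant_limit(self):
        for r0 in (0.01, 0.05, 0.2):
            assert stiffness(r0, 0.0, -100.0, 5.0e4) == 5.0e4

    def test_radius_dependent_hand_value(self):
        # f1 exp(f2 r0) + f3 at plausible posterior-median values
        assert stiffness(0.05, 5.26e6, -162.0, 5.17e4) == \
            pytest.approx(5.33e4, rel=2e-3)

    def test_steep_decay_limit(self):
        assert stiffness(0.05, 5.26e6, -1e4, 5.17e4) == \
            pytest.approx(5.17e4, rel=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            stiffness(0.05, -1e6, 0.0, 1e4)


class TestWallPressure:
    def test_zero_at_unstressed_area_both_laws(self):
        A0 = math.pi * 0.05 ** 2
        lin = WallModel(kind="linear", f3=5.0e4)
        non = WallModel(kind="nonlinear", f3=9.0e4, gamma=4.0)
        assert wall_pressure(A0, A0, lin, 0.05) == 0.0
        assert wall_pressure(A0, A0, non, 0.05) == 0.0

    def test_linear_hand_value(self):
        A0 = math.pi * 0.05 ** 2
        wall = WallModel(kind="linear", f3=5.17e4)
        p = wall_pressure(1.21 * A0, A0, wall, 0.05)
        assert p == pytest.approx((4 / 3) * 5.17e4 * 0.1 / 1333.22, rel=1e-12)
        assert p == pytest.approx(5.17, rel=1e-3)

    def test_nonlinear_hand_value(self):
        A0 = math.pi * 0.05 ** 2
        wall = WallModel(kind="nonlinear", f3=9.17e4, gamma=5.18)
        p = wall_pressure(1.1 * A0, A0, wall, 0.05)
        expected = 9.17e4 * math.tan((math.pi / 5.18) * 0.1) / 1333.22
        assert p == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(4.18, rel=1e-2)

    def test_tangent_domain_guard(self):
        A0 = 1.0
        wall = WallModel(kind="nonlinear", f3=9.0e4, gamma=4.0)
        with pytest.raises(DomainError, match="tangent"):
            wall_pressure(A0 * (1 + 4.0 / 2 + 0.01), A0, wall, 0.05)

    @pytest.mark.parametrize("wall", [
        WallModel(kind="linear", f3=5.17e4),
        WallModel(kind="nonlinear", f3=9.17e4, gamma=5.18),
    ])
    def test_exact_inversion(self, wall):
        A0 = math.pi * 0.047 ** 2
        A = A0 * np.array([0.8, 0.95, 1.0, 1.1, 1.3])
        p = wall_pressure(A, A0, wall, 0.047)
        np.testing.assert_allclose(
            area_from_pressure(p, A0, wall, 0.047), A, rtol=1e-12)

    def test_vessel_specific_lookup(self):
        wall = WallModel(kind="linear", stiffness_mode="vessel_specific",
                         chi_per_vessel={1: 4.0e4, 2: 6.0e4})
        A0 = 1.0
        p1 = wall_pressure(1.21, A0, wall, 0.05, vessel_id=1)
        p2 = wall_pressure(1.21, A0, wall, 0.05, vessel_id=2)
        assert p2 == pytest.approx(1.5 * p1, rel=1e-12)
        with pytest.raises(DomainError):
            wall_pressure(1.21, A0, wall, 0.05, vessel_id=9)


class TestWallModelValidation:
    def test_constant_mode_requires_zero_f1(self):
        with pytest.raises(ConfigurationError):
            WallModel(kind="linear", stiffness_mode="constant", f1=1.0)

    def test_nonlinear_needs_gamma(self):
        with pytest.raises(ConfigurationError):
            WallModel(kind="nonlinear", f3=9e4)


class TestBoundaryLayer:
    def test_mouse_value(self, constants):
        assert boundary_layer_thickness(constants) == \
            pytest.approx(math.sqrt(0.049 * 0.11 / (2 * math.pi * 1.055)),
                          rel=1e-12)
        assert boundary_layer_thickness(constants) == \
            pytest.approx(0.0285, rel=2e-3)

    def test_sqrt_scaling_in_period(self):
        d1 = boundary_layer_thickness(PhysicalConstants(T=0.11))
        d2 = boundary_layer_thickness(PhysicalConstants(T=0.44))
        assert d2 == pytest.approx(2.0 * d1, rel=1e-12)


@pytest.fixture(scope="module")
def rest_run(single_vessel, constants):
    t = np.linspace(0, constants.T, 64, endpoint=False)
    wall = WallModel(kind="linear", f3=5.17e4)
    wk = NominalWindkessel([1], [2e4], [8e4], [0.025 / 8e4])
    grid = SimulationGrid(dx=0.02, dt=5e-5, n_cycles=2)
    fields = simulate(single_vessel, wall, wk, (t, np.zeros_like(t)),
                      grid, constants)
    return fields, wall, grid


class TestSolverBasics:
    def test_rest_state_is_fixed_point(self, rest_run):
        fields, _, _ = rest_run
        assert np.all(fields.p[0] == 0.0)
        assert np.all(fields.q[0] == 0.0)

    def test_cfl_closed_form_at_rest(self, rest_run, constants):
        fields, wall, grid = rest_run
        ok, cour = check_cfl(grid, fields, wall, constants)
        c0 = math.sqrt(2 * 5.17e4 / (3 * constants.rho))
        dx = fields.x[0][1] - fields.x[0][0]
        assert ok
        assert cour == pytest.approx(grid.dt * c0 / dx, rel=1e-9)

    def test_cfl_scaling_with_dt(self, rest_run, constants):
        fields, wall, grid = rest_run
        _, cour = check_cfl(grid, fields, wall, constants)
        tiny = SimulationGrid(dx=grid.dx, dt=grid.dt / 100, n_cycles=1)
        ok2, cour2 = check_cfl(tiny, fields, wall, constants)
        assert ok2 and cour2 == pytest.approx(cour / 100, rel=1e-9)

    def test_windkessel_steady_state(self, single_vessel, constants):
        R1, R2, C = 2e4, 8e4, 0.025 / 8e4
        q0 = 0.25
        t = np.linspace(0, constants.T, 64, endpoint=False)
        wall = WallModel(kind="linear", f3=5.17e4)
        wk = NominalWindkessel([1], [R1], [R2], [C])
        grid = SimulationGrid(dx=0.02, dt=5e-5, n_cycles=40,
                              convergence_tol=1e-8)
        f = simulate(single_vessel, wall, wk, (t, np.full_like(t, q0)),
                     grid, constants)
        expected = q0 * (R1 + R2) / constants.conv
        assert f.p[0][:, -1].mean() == pytest.approx(expected, rel=1e-5)

    def test_deterministic(self, tree3, wk3, mouse_inflow, constants):
        wall = WallModel(kind="linear", f3=5.17e4)
        grid = SimulationGrid(dx=0.05, dt=stable_dt(tree3, wall, 0.05),
                              n_cycles=4)
        a = simulate(tree3, wall, wk3, mouse_inflow, grid, constants)
        b = simulate(tree3, wall, wk3, mouse_inflow, grid, constants)
        for i in range(3):
            np.testing.assert_array_equal(a.p[i], b.p[i])

    def test_warm_start_matches_cold(self, tree3, wk3, mouse_inflow,
                                     constants):
        wall = WallModel(kind="linear", f3=5.17e4)
        grid = SimulationGrid(dx=0.05, dt=stable_dt(tree3, wall, 0.05),
                              n_cycles=10, convergence_tol=1e-4)
        cold = simulate(tree3, wall, wk3, mouse_inflow, grid, constants)
        warm = simulate(tree3, wall, wk3, mouse_inflow, grid, constants,
                        init_state=cold.final_state)
        assert warm.n_cycles_run <= cold.n_cycles_run
        assert np.max(np.abs(warm.pressure_series(1)
                             - cold.pressure_series(1))) < 0.02

    def test_cfl_violation_aborts(self, tree3, wk3, mouse_inflow, constants):
        wall = WallModel(kind="linear", f3=5.17e4)
        grid = SimulationGrid(dx=0.05, dt=4e-4, n_cycles=2)
        with pytest.raises(SolverError, match="CFL"):
            simulate(tree3, wall, wk3, mouse_inflow, grid, constants)

    def test_missing_windkessel_rejected(self, tree3, mouse_inflow,
                                         constants):
        wall = WallModel(kind="linear", f3=5.17e4)
        wk = NominalWindkessel([2], [1e4], [4e4], [1e-6])
        grid = SimulationGrid(dx=0.05, dt=1e-4, n_cycles=2)
        with pytest.raises(ConfigurationError, match="missing"):
            simulate(tree3, wall, wk, mouse_inflow, grid, constants)
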