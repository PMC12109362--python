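"""Finite-volume SIMPLE solver: benchmarks, invariances, limits."""

import numpy as np
import pytest

import stentflow as sf
from stentflow import postprocess as pp
from stentflow.geometry import SOLID, WALL
from stentflow.solver import (SolverDivergenceError, load_solver_config,
                              save_solver_config)


def small_channel(h=2.0, L1=150):
    geom = sf.make_channel(30, L1)
    mask = sf.rasterize(geom, sf.GridSpec(h=h))
    return geom, mask


class TestPoiseuille:
    """Plane Poiseuille flow is the analytic anchor for the discretization."""

    def test_max_over_mean_ratio(self, poiseuille):
        field, mask, geom = poiseuille
        prof = field.u[1:-1, -2]  # fluid rows at the outlet face column
        assert prof.max() / prof.mean() == pytest.approx(1.5, rel=0.02)

    def test_parabolic_profile_l2_error(self, poiseuille):
        field, mask, geom = poiseuille
        h = mask.h
        prof = field.u[1:-1, -2]
        y = (np.arange(len(prof)) + 0.5) * h
        w = geom.D1
        u_bulk = prof.mean()
        exact = 6 * u_bulk * (y / w) * (1 - y / w)
        err = np.linalg.norm(prof - exact) / np.linalg.norm(exact)
        assert err <= 0.02

    def test_mass_conservation(self, poiseuille):
        field, mask, _ = poiseuille
        q_in = pp.boundary_flux(field, mask, "inlet")
        q_out = pp.boundary_flux(field, mask, "aortic_outlet")
        assert abs(q_in - q_out) / q_in <= 1e-6


class TestGlobalMass:
    def test_branch_case_conserves_mass(self, branch_run):
        _, field, mask = branch_run
        q_in = pp.boundary_flux(field, mask, "inlet")
        q_a = pp.boundary_flux(field, mask, "aortic_outlet")
        q_b = pp.boundary_flux(field, mask, "branch_outlet")
        assert abs(q_in - (q_a + q_b)) / q_in <= 1e-6

    def test_no_slip_on_blocked_faces(self, branch_run):
        _, field, mask = branch_run
        blocked = (mask.labels == WALL) | (mask.labels == SOLID)
        # u faces flanked by a blocked cell on the fluid side boundary
        fl = mask.labels == 0
        wall_u = (fl[:, :-1] & blocked[:, 1:]) | (blocked[:, :-1] & fl[:, 1:])
        jj, ii = np.nonzero(wall_u)
        assert np.all(field.u[jj, ii + 1] == 0.0)


class TestInvariances:
    def test_pressure_gauge_invariance(self):
        geom, mask = small_channel()
        fluid = sf.scale_reynolds(sf.FluidProperties(),
                                  sf.BoundaryConditions(), geom, 100.0)
        st = sf.SolverSettings(tol=1e-6, max_iter=3000)
        f0 = sf.solve_steady(mask, fluid,
                             sf.BoundaryConditions(p_outlet=0.0), st)
        f1 = sf.solve_steady(mask, fluid,
                             sf.BoundaryConditions(p_outlet=13300.0), st)
        assert np.max(np.abs(f1.u - f0.u)) < 1e-10
        assert np.max(np.abs(f1.v - f0.v)) < 1e-10
        assert f1.p - f0.p == pytest.approx(13300.0)

    def test_bit_identical_reruns(self):
        geom, mask = small_channel()
        fluid = sf.scale_reynolds(sf.FluidProperties(),
                                  sf.BoundaryConditions(), geom, 150.0)
        st = sf.SolverSettings(tol=1e-5, max_iter=2000)
        f1 = sf.solve_steady(mask, fluid, sf.BoundaryConditions(), st)
        f2 = sf.solve_steady(mask, fluid, sf.BoundaryConditions(), st)
        assert np.array_equal(f1.residual_history, f2.residual_history)
        assert np.array_equal(f1.u, f2.u)

    def test_converged_flag_means_mass_below_tol(self, branch_run):
        _, field, _ = branch_run
        assert field.converged
        assert field.residual_history[-1, 0] <= field.settings.tol

    def test_upwind_scheme_also_converges(self):
        geom, mask = small_channel()
        fluid = sf.scale_reynolds(sf.FluidProperties(),
                                  sf.BoundaryConditions(), geom, 100.0)
        st = sf.SolverSettings(tol=1e-5, max_iter=3000,
                               convection_scheme="upwind")
        f = sf.solve_steady(mask, fluid, sf.BoundaryConditions(), st)
        assert f.converged
        prof = f.u[1:-1, -2]
        assert prof.max() / prof.mean() == pytest.approx(1.5, rel=0.05)


class TestReynoldsScaling:
    def test_nominal_reynolds_is_near_7234(self):
        geom = sf.make_channel(30, 300)
        Re = sf.reynolds_number(sf.FluidProperties(),
                                sf.BoundaryConditions(), geom)
        assert Re == pytest.approx(1055 * 0.8 * 0.03 / 0.0035, rel=1e-12)

    def test_scaling_to_nominal_is_identity(self):
        geom = sf.make_channel(30, 300)
        fl = sf.FluidProperties()
        Re0 = sf.reynolds_number(fl, sf.BoundaryConditions(), geom)
        back = sf.scale_reynolds(fl, sf.BoundaryConditions(), geom, Re0)
        assert back.mu == pytest.approx(0.0035)

    def test_closed_form_target(self):
        geom = sf.make_channel(30, 300)
        fl = sf.scale_reynolds(sf.FluidProperties(), sf.BoundaryConditions(),
                               geom, 200.0)
        assert fl.mu == pytest.approx(1055 * 0.8 * 0.03 / 200)
        assert fl.rho == 1055

    def test_invalid_target_rejected(self):
        geom = sf.make_channel(30, 300)
        with pytest.raises(ValueError):
            sf.scale_reynolds(sf.FluidProperties(), sf.BoundaryConditions(),
                              geom, -1.0)


class TestStokesLimit:
    def test_simple_matches_direct_stokes_solve(self):
        # creeping flow: the SIMPLE loop must agree with a monolithic linear
        # solve of the same discretization within 1% in branch flux
        geom = sf.make_geometry(30, 16, 150, 80, 90.0, 8.0)
        mask = sf.rasterize(geom, sf.GridSpec(h=2.0))
        bcs = sf.BoundaryConditions()
        fluid = sf.scale_reynolds(sf.FluidProperties(), bcs, geom, 0.5)
        simple = sf.solve_steady(mask, fluid, bcs,
                                 sf.SolverSettings(tol=1e-7, max_iter=6000))
        direct = sf.solve_stokes_direct(mask, fluid, bcs)
        q_simple = pp.boundary_flux(simple, mask, "branch_outlet")
        q_direct = pp.boundary_flux(direct, mask, "branch_outlet")
        assert q_simple == pytest.approx(q_direct, rel=0.01)


class TestGridConvergence:
    def test_channel_flux_imposed_by_inlet(self):
        geom = sf.make_channel(30, 150)
        bcs = sf.BoundaryConditions()
        fluid = sf.scale_reynolds(sf.FluidProperties(), bcs, geom, 100.0)
        rep = sf.check_grid_convergence(geom, fluid, bcs,
                                        sf.SolverSettings(tol=1e-6,
                                                          max_iter=3000),
                                        [3.0, 2.0, 1.0])
        assert len(rep) == 3
        flux = rep["flux"].to_numpy()
        assert np.all(np.abs(flux - flux[0]) / flux[0] <= 1e-6)

    def test_branch_flux_sign_stable_under_refinement(self):
        # wide no-stent branch so three admissible grids stay coarse
        geom = sf.make_geometry(30, 16, 150, 80, 135.0, 0.0,
                                stent_present=False)
        bcs = sf.BoundaryConditions()
        fluid = sf.scale_reynolds(sf.FluidProperties(), bcs, geom, 200.0)
        rep = sf.check_grid_convergence(geom, fluid, bcs,
                                        sf.SolverSettings(tol=1e-5,
                                                          max_iter=4000),
                                        [2.0, 1.5, 1.0])
        assert rep.attrs["sign_stable"]
        assert len(rep) == 3

    def test_bad_h_list_rejected(self):
        geom = sf.make_channel(30, 150)
        with pytest.raises(ValueError, match="decreasing"):
            sf.check_grid_convergence(geom, sf.FluidProperties(),
                                      sf.BoundaryConditions(),
                                      sf.SolverSettings(), [1.0, 2.0, 3.0])


class TestErrorsAndConfig:
    def test_divergence_error_carries_iteration(self):
        err = SolverDivergenceError(42, 1e9)
        assert err.iteration == 42
        assert "42" in str(err)

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            sf.SolverSettings(relax_momentum=1.5)
        with pytest.raises(ValueError):
            sf.SolverSettings(convection_scheme="quick")

    def test_solver_config_round_trip(self, tmp_path):
        st = sf.SolverSettings(relax_momentum=0.6, relax_pressure=0.2,
                               tol=1e-6, max_iter=1234,
                               convection_scheme="upwind")
        path = save_solver_config(st, 250.0, tmp_path / "solver.cfg")
        st2, re = load_solver_config(path)
        assert re == 250.0
        assert st2.relax_momentum == 0.6 and st2.max_iter == 1234
        assert st2.convection_scheme == "upwind"

    def test_run_log_reports_both_reynolds_numbers(self, branch_run):
        _, field, _ = branch_run
        log = field.run_log()
        assert log["reynolds"] == pytest.approx(200.0, rel=1e-6)
        assert log["nominal_reynolds"] == pytest.approx(7234, rel=0.01)

    def test_field_exports(self, branch_run, tmp_path):
        _, field, _ = branch_run
        vtk = field.to_vtk(tmp_path / "field.vtk")
        assert "STRUCTURED_POINTS" in open(vtk).read(200)
        csv = field.residuals_to_csv(tmp_path / "residuals.csv")
        assert "mass" in open(csv).readline()
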