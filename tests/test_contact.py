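"""Rigid-probe contact: gap function, indentation solves, force
properties."""

import numpy as np
import pytest

from tonofem import fem as F
from tonofem import geometry as G
from tonofem.contact import (
    IndentationSolver,
    probe_gap,
    solve_indentation,
)


class TestProbeGap:
    def test_touching_apex_zero_gap(self):
        probe = G.ProbeSpec(diameter=1.7)
        g = probe_gap(probe, 0.0, np.array([[0.0, 0.0, 0.0]]))
        assert g[0] == pytest.approx(0.0, abs=1e-14)

    def test_outside_radius_no_candidate(self):
        probe = G.ProbeSpec(diameter=1.7)
        g = probe_gap(probe, 0.5, np.array([[0.0, 1.0, 0.0]]))
        assert np.isinf(g[0])

    def test_depth_translates_rigidly(self):
        probe = G.ProbeSpec(diameter=1.7)
        g = probe_gap(probe, 0.3, np.array([[0.0, 0.2, 0.1]]))
        assert g[0] == pytest.approx(-0.3)

    def test_displacement_closes_gap(self):
        probe = G.ProbeSpec(diameter=1.7)
        g = probe_gap(probe, 0.3, np.array([[0.0, 0.0, 0.0]]),
                      displacement=np.array([[0.3, 0.0, 0.0]]))
        assert g[0] == pytest.approx(0.0, abs=1e-14)

    def test_fillet_recedes_rim(self):
        probe = G.ProbeSpec(diameter=1.7, edge_fillet_radius=0.2)
        centre = probe_gap(probe, 0.0, np.array([[0.0, 0.0, 0.0]]))
        rim = probe_gap(probe, 0.0, np.array([[0.0, 0.84, 0.0]]))
        assert rim[0] > centre[0]


class TestIndentationSolve:
    def test_zero_depth_zero_force_any_iop(self, eye_solver_medium):
        for iop in (0.0, 10.0, 20.0):
            case = F.LoadCase(iop_mmhg=iop, target_depth=0.0)
            res = eye_solver_medium.solve(case, recover=False)
            assert res.reaction_force == 0.0
            assert res.history[0] == (0, 0.0, 0.0, 0, 0)

    def test_force_history_starts_at_zero_and_grows(self, eye_solver_medium):
        case = F.LoadCase(iop_mmhg=20.0, target_depth=0.5, n_increments=5)
        res = eye_solver_medium.solve(case, recover=False)
        forces = [h[2] for h in res.history]
        assert forces[0] == 0.0
        assert forces[-1] == max(forces)
        assert res.reaction_force == pytest.approx(forces[-1])

    def test_force_monotone_in_depth_and_iop(self, eye_solver_medium):
        """Across the study grid, the applanation force increases with
        plunging depth at fixed IOP and with IOP at fixed depth."""
        depths = (0.3, 0.5, 0.7)
        iops = (10.0, 15.0, 20.0)
        table = {}
        for iop in iops:
            for d in depths:
                case = F.LoadCase(iop_mmhg=iop, target_depth=d, n_increments=5)
                table[(iop, d)] = eye_solver_medium.solve(
                    case, recover=False
                ).reaction_force
        for iop in iops:
            f = [table[(iop, d)] for d in depths]
            assert f[0] < f[1] < f[2]
        for d in depths:
            f = [table[(iop, d)] for iop in iops]
            assert f[0] < f[1] < f[2]

    def test_penalty_insensitivity(self, eye_solver_medium):
        """A 10x stiffer penalty changes the force by < 1%."""
        case = F.LoadCase(iop_mmhg=20.0, target_depth=0.5, n_increments=5)
        f1 = eye_solver_medium.solve(case, recover=False).reaction_force
        f2 = eye_solver_medium.solve(
            case, recover=False,
            penalty_scale=10 * eye_solver_medium.penalty_scale,
        ).reaction_force
        assert abs(f2 - f1) / f1 < 0.01

    def test_no_tensile_contact_and_penetration_bound(self, eye_solver_medium):
        case = F.LoadCase(iop_mmhg=20.0, target_depth=0.5)
        res = eye_solver_medium.solve(case, recover=False)
        state = res.contact
        pen = -state.gap[state.active_points]
        assert pen.max(initial=0.0) < 1e-4
        # active-point forces are compressive (gap <= 0 <-> pushing)
        assert np.all(state.gap[state.active_points] <= 1e-12)
        # and total equals the nodal force sum along the axis
        assert res.reaction_force == pytest.approx(
            state.nodal_force.sum(), abs=1e-10
        )

    def test_imbert_fick_lower_bound(self, eye_solver_medium):
        """At full applanation the force exceeds IOP x contact area (the
        cornea's own stiffness adds to the ideal applanation force)."""
        case = F.LoadCase(iop_mmhg=20.0, target_depth=0.7)
        res = eye_solver_medium.solve(case, recover=False)
        p = case.pressure_mpa
        a = case.probe.radius
        assert res.reaction_force > p * np.pi * a * a

    def test_probe_size_near_independence(self, eye_solver_quadratic):
        """1.7 mm and 3.06 mm probes at equal depth/IOP: forces within
        35% of each other (bending-dominated shell indentation depends
        only weakly on the punch radius)."""
        f = {}
        for name in ("standard", "goldmann"):
            case = F.LoadCase(iop_mmhg=20.0, probe=G.PROBE_PRESETS[name],
                              target_depth=0.5, n_increments=5)
            f[name] = eye_solver_quadratic.solve(
                case, recover=False).reaction_force
        assert abs(f["standard"] - f["goldmann"]) / f["goldmann"] < 0.35

    def test_max_deformation_at_probe_rim(self, eye_solver_medium):
        """The maximum total deformation sits on the cornea within 1.5
        probe radii of the probe rim, and exceeds the imposed depth."""
        case = F.LoadCase(iop_mmhg=20.0, target_depth=0.7)
        res = eye_solver_medium.solve(case, recover=False)
        dmax, loc = res.max_total_deformation
        assert dmax >= 0.7
        r = np.hypot(loc[1], loc[2])
        a = case.probe.radius
        assert abs(r - a) <= 1.5 * a

    def test_solver_reuse_matches_fresh_solve(self, eye_mesh_coarse,
                                              materials):
        case = F.LoadCase(iop_mmhg=15.0, target_depth=0.4, n_increments=4)
        fresh = solve_indentation(eye_mesh_coarse, materials, case,
                                  recover=False)
        solver = IndentationSolver(eye_mesh_coarse, materials)
        again = solver.solve(case, recover=False)
        assert fresh.reaction_force == pytest.approx(again.reaction_force,
                                                     rel=1e-12)

    def test_updated_geometry_close_to_linear_at_small_depth(
        self, eye_mesh_coarse, materials
    ):
        """The geometrically updated mode reduces to the small-strain
        solution for small plunging depths."""
        case = F.LoadCase(iop_mmhg=10.0, target_depth=0.1, n_increments=3)
        lin = solve_indentation(eye_mesh_coarse, materials, case,
                                recover=False)
        upd = solve_indentation(eye_mesh_coarse, materials, case,
                                updated_geometry=True)
        assert upd.reaction_force == pytest.approx(
            lin.reaction_force, rel=0.15
        )

    def test_constraint_mode_mismatch_rejected(self, eye_solver_medium):
        case = F.LoadCase(iop_mmhg=10.0, target_depth=0.3,
                          constraint_mode="posterior-patch")
        with pytest.raises(Exception, match="constraint mode"):
            eye_solver_medium.solve(case)


class TestFlatPunchOracle:
    def test_force_within_five_percent_of_boussinesq(self):
        """The contact pipeline reproduces F = 2 a E d / (1 - nu^2) on the
        rim-graded half-space fixture within 5%."""
        from tonofem.verification import fe_flat_punch

        out = fe_flat_punch()
        assert out["rel_err"] < 0.05

    def test_block_fixture_reaches_cartesian_limit(self):
        """On the Cartesian block fixture the punch rim is resolved only
        to the grid pitch; the force should still fall within ~15% of the
        closed form at moderate resolution."""
        from tonofem.verification import fe_flat_punch

        out = fe_flat_punch(fixture="block", domain=40.0, h_fine=0.12)
        assert out["rel_err"] < 0.15
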