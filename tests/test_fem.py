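"""Shell FEM: element benchmark, toy oracles, viscoelasticity, invariants."""
import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

import craniospring.fem_spring as F
from craniospring.errors import (ConfigurationError, ConstraintError,
                                 NonConvergenceError, ReportError)
from craniospring.shell import dkt_bending, elastic_matrices
from craniospring.types import Material, SpringElement

from conftest import flap_oracle_opening, two_flap_toy

RAMP = np.array([0.25, 0.5, 0.75, 1.0])


def solve_elastic(system, springs):
    return F.solve_quasistatic(system, springs, RAMP, crimped_opening=0.0)


class TestDKTElement:
    def test_rigid_body_modes_are_stress_free(self):
        xy = np.array([[[0.0, 0.0], [2.0, 0.2], [0.5, 1.7]]])
        x, y = xy[:, :, 0], xy[:, :, 1]
        _, db = elastic_matrices(np.array([1000.0]), np.array([0.3]), 1.0)
        K = dkt_bending(x, y, db)[0]
        modes = [
            np.array([1, 0, 0, 1, 0, 0, 1, 0, 0], float),               # w
            np.array([y[0, 0], 1, 0, y[0, 1], 1, 0, y[0, 2], 1, 0]),    # rx
            np.array([-x[0, 0], 0, 1, -x[0, 1], 0, 1, -x[0, 2], 0, 1]), # ry
        ]
        for mode in modes:
            assert np.abs(K @ mode).max() < 1e-9 * np.abs(K).max()

    def test_clamped_plate_point_load_benchmark(self):
        """Kirchhoff series: w_c = 0.005612 P a^2 / D, within 5% at 2k elems."""
        a, E, nu, t, P = 100.0, 1000.0, 0.3, 1.0, 1.0
        nn = 32
        xs = np.linspace(0, a, nn + 1)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        nodes = np.column_stack([X.ravel(), Y.ravel()])

        def nid(i, j):
            return i * (nn + 1) + j
        faces = []
        for i in range(nn):
            for j in range(nn):
                faces += [[nid(i, j), nid(i + 1, j), nid(i + 1, j + 1)],
                          [nid(i, j), nid(i + 1, j + 1), nid(i, j + 1)]]
        faces = np.array(faces)
        assert len(faces) == 2048
        x = nodes[faces][:, :, 0]
        y = nodes[faces][:, :, 1]
        _, db = elastic_matrices(np.full(len(faces), E),
                                 np.full(len(faces), nu), t)
        ke = dkt_bending(x, y, db)
        ndof = 3 * len(nodes)
        rows, cols, vals = [], [], []
        for e, f in enumerate(faces):
            dofs = np.concatenate([[3 * v, 3 * v + 1, 3 * v + 2] for v in f])
            r, c = np.meshgrid(dofs, dofs, indexing="ij")
            rows.append(r.ravel())
            cols.append(c.ravel())
            vals.append(ke[e].ravel())
        K = sp.coo_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(ndof, ndof)).tocsr()
        fixed = np.zeros(ndof, bool)
        for i in range(nn + 1):
            for j in (0, nn):
                fixed[3 * nid(i, j):3 * nid(i, j) + 3] = True
                fixed[3 * nid(j, i):3 * nid(j, i) + 3] = True
        free = np.flatnonzero(~fixed)
        rhs = np.zeros(ndof)
        centre = nid(nn // 2, nn // 2)
        rhs[3 * centre] = P
        u = np.zeros(ndof)
        u[free] = spsolve(K[free][:, free].tocsc(), rhs[free])
        D = E * t**3 / 12 / (1 - nu**2)
        w_ref = 0.005612 * P * a**2 / D
        assert u[3 * centre] == pytest.approx(w_ref, rel=0.05)


class TestSpringForce:
    def test_zero_at_free_length(self):
        s = SpringElement("S12", stiffness=0.31, node_a=0, node_b=1)
        assert F.spring_force(s, 60.0) == 0.0

    def test_linear_ratio(self):
        s = SpringElement("S12", stiffness=0.31, node_a=0, node_b=1)
        assert F.spring_force(s, 30.0) == pytest.approx(
            2.0 * F.spring_force(s, 45.0))

    def test_no_pull_beyond_free_length(self):
        s = SpringElement("S12", stiffness=0.31, node_a=0, node_b=1)
        assert F.spring_force(s, 70.0) == 0.0

    def test_negative_opening_raises(self):
        s = SpringElement("S12", stiffness=0.31, node_a=0, node_b=1)
        with pytest.raises(ConfigurationError):
            F.spring_force(s, -1.0)


class TestQuasistaticToy:
    def test_no_springs_zero_displacement(self):
        system, _, _ = two_flap_toy()
        sol = F.solve_quasistatic(system, [], RAMP, crimped_opening=0.0)
        assert np.abs(sol.displacements).max() == 0.0

    def test_elastic_solution_is_time_independent(self):
        system, springs, _ = two_flap_toy(stiffness=0.05)
        sched = np.concatenate([RAMP, [100.0, 432000.0]])
        sol = F.solve_quasistatic(system, springs, sched, crimped_opening=0.0)
        # purely elastic: t = 1 s equals the 5-day solution
        assert sol.opening_at(432000.0)[0] == pytest.approx(
            sol.opening_at(1.0)[0], rel=1e-6)

    def test_equilibrium_matches_one_dof_energy_oracle(self):
        system, springs, params = two_flap_toy(stiffness=0.02)
        sol = solve_elastic(system, springs)
        assert sol.opening_at(1.0)[0] == pytest.approx(
            flap_oracle_opening(params), rel=0.01)

    def test_linearity_in_youngs_modulus(self):
        _, _, params = two_flap_toy()
        openings = {}
        for E in (400.0, 800.0):
            system, springs, p = two_flap_toy(stiffness=0.002, youngs=E)
            sol = solve_elastic(system, springs)
            openings[E] = sol.opening_at(1.0)[0] - p["d0"]
        # doubling E halves the (small) deflection
        assert openings[400.0] == pytest.approx(2 * openings[800.0],
                                                rel=0.02)

    def test_force_balance_at_constrained_nodes(self):
        system, springs, _ = two_flap_toy(stiffness=0.1)
        sol = solve_elastic(system, springs)
        reactions, applied, scale = F.reaction_balance(sol, 1.0)
        assert np.linalg.norm(reactions + applied) < 1e-6 * scale

    def test_long_time_viscoelastic_matches_relaxed_modulus(self):
        prony = ((0.5, 3000.0),)
        system_v, springs, params = two_flap_toy(stiffness=0.05, prony=prony)
        sched = np.concatenate([RAMP, np.geomspace(1.0, 432000.0, 25)[1:]])
        sol_v = F.solve_quasistatic(system_v, springs, sched,
                                    crimped_opening=0.0)
        # relaxed-modulus oracle: elastic solve at E_inf = E (1 - sum g)
        system_r, springs_r, params_r = two_flap_toy(
            stiffness=0.05, youngs=params["youngs"] * 0.5)
        sol_r = F.solve_quasistatic(system_r, springs_r, RAMP,
                                    crimped_opening=0.0)
        d_v = sol_v.opening_at(432000.0)[0] - params["d0"]
        d_r = sol_r.opening_at(1.0)[0] - params["d0"]
        assert d_v == pytest.approx(d_r, rel=0.02)

    def test_creep_monotone_and_bounded(self):
        prony = ((0.5, 3000.0),)
        system, springs, _ = two_flap_toy(stiffness=0.05, prony=prony)
        sched = np.concatenate([RAMP, np.geomspace(1.0, 432000.0, 15)[1:]])
        sol = F.solve_quasistatic(system, springs, sched, crimped_opening=0.0)
        assert (np.diff(sol.openings[:, 0]) >= -1e-4).all()
        assert (sol.openings <= 60.0 + 1e-6).all()

    def test_monotone_stiffness_ordering(self):
        finals = []
        for k in (0.01, 0.02, 0.04):      # S10 < S12 < S14 surrogate
            system, springs, _ = two_flap_toy(stiffness=k)
            sol = solve_elastic(system, springs)
            finals.append(sol.opening_at(1.0)[0])
        assert finals[0] < finals[1] < finals[2]

    def test_mesh_refinement_consistency(self):
        res = []
        for nz, ny in ((8, 2), (16, 4)):
            system, springs, _ = two_flap_toy(stiffness=0.02, nz=nz, ny=ny)
            sol = solve_elastic(system, springs)
            res.append(sol.opening_at(1.0)[0])
        assert abs(res[1] / res[0] - 1) < 0.02

    def test_energy_consistency_elastic(self):
        """Work done by the spring along the quasi-static path equals the
        strain energy stored (elastic case: no dissipation)."""
        system, springs, params = two_flap_toy(stiffness=0.02)
        sched = np.linspace(0.0, 1.0, 11)[1:]     # fine ramp for the path sum
        sol = F.solve_quasistatic(system, springs, sched, crimped_opening=0.0)
        # path work: trapezoid of (ramped) spring force over the opening
        spr = springs[0]
        lam = np.minimum(sol.times, 1.0)
        force = lam * np.maximum(0.0, spr.stiffness
                                 * (spr.free_length - sol.openings[:, 0]))
        work = np.trapezoid(force, sol.openings[:, 0])
        # strain energy of the (linear-regime) structure: 0.5 f_ext . u
        ut = sol.displacement_at(1.0)
        f_ext, _, _ = F._spring_loads(springs, system.nodes + ut, 1.0)
        stored = 0.5 * np.einsum("ni,ni->", f_ext[:, :3], ut)
        assert stored == pytest.approx(work, rel=0.01)

    def test_nonconvergence_reports_last_time(self):
        system, springs, _ = two_flap_toy(stiffness=0.1)
        with pytest.raises(NonConvergenceError) as err:
            F.solve_quasistatic(system, springs, RAMP, max_iter=1,
                                crimped_opening=0.0)
        assert err.value.last_converged_time is None

    def test_crimped_opening_sanity(self):
        system, springs, _ = two_flap_toy()
        with pytest.raises(ConfigurationError, match="crimped"):
            F.solve_quasistatic(system, springs, RAMP, crimped_opening=55.0)


class TestAssemble:
    def test_no_constraints_raises(self):
        from craniospring.fem_spring import FESystem
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]])
        f = np.array([[0, 1, 2]])
        with pytest.raises(ConstraintError):
            FESystem.from_arrays(v, f, Material(youngs_modulus=1.0,
                                                poisson=0.3),
                                 1.0, np.array([], dtype=int))

    def test_assemble_skull_model(self, coarse_model):
        system = F.assemble(coarse_model)
        assert system.n_elements == coarse_model.shell.n_faces
        assert system.fixed.sum() > 0
        # sutures must be softer than bone in the element table
        sel_sut = np.isin(coarse_model.shell.face_labels,
                          ["coronal_suture", "lambdoid_suture"])
        k_sut = np.abs(system.kloc[sel_sut]).max()
        k_bone = np.abs(system.kloc[~sel_sut]).max()
        assert k_sut < k_bone

    def test_unlabeled_shell_raises(self, coarse_head):
        from craniospring.errors import AssemblyError
        head, landmarks = coarse_head

        class Dummy:
            pass
        from craniospring import PopulationParams, build_s_model
        model = build_s_model(head, landmarks, PopulationParams())
        model.shell.face_labels = None
        with pytest.raises(AssemblyError):
            F.assemble(model)

    def test_missing_material_raises(self, coarse_model):
        from craniospring.errors import AssemblyError
        with pytest.raises(AssemblyError):
            F.assemble(coarse_model, materials={
                "skull": F.DEFAULT_MATERIALS["skull"]})


class TestExtractOutputs:
    def test_zero_displacement_keeps_ci(self):
        system, springs, _ = two_flap_toy()
        sched = np.concatenate([RAMP, [432000.0]])
        sol = F.solve_quasistatic(system, [], sched, crimped_opening=0.0)
        assert np.abs(sol.displacements).max() == 0.0

    def test_missing_timepoint_raises(self):
        system, springs, _ = two_flap_toy()
        sol = F.solve_quasistatic(system, springs, RAMP, crimped_opening=0.0)
        import craniospring.geometry as G
        frame = G.make_frame([0, 60, 0], [-45, 0, 0], [45, 0, 0])
        with pytest.raises(ReportError):
            F.extract_outputs(sol, frame)    # no FU snapshot, no shell

    def test_schedule_validation(self):
        system, springs, _ = two_flap_toy()
        with pytest.raises(ConfigurationError):
            F.solve_quasistatic(system, springs, np.array([0.0, 1.0]))
        with pytest.raises(ConfigurationError):
            F.solve_quasistatic(system, springs, np.array([2.0, 1.0]))


class TestMaterialType:
    def test_prony_sum_validated(self):
        with pytest.raises(ValueError):
            Material(youngs_modulus=100.0, poisson=0.3,
                     prony_terms=((0.6, 10.0), (0.5, 100.0)))

    def test_long_term_modulus(self):
        m = Material(youngs_modulus=100.0, poisson=0.3,
                     prony_terms=((0.4, 10.0),))
        assert m.long_term_modulus == pytest.approx(60.0)
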