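"""Element stiffness, patch tests, closed-form oracles, contact, trusses."""

import numpy as np
import pytest

from kneefem.materials import MaterialField
from kneefem.mesh import Mesh, box_mesh, grid_lines
from kneefem.model import (
    BoundaryConditions,
    KneeModel,
    TrussLaw,
    cruciate_collateral_law,
)
from kneefem.solver import (
    SolverError,
    contact_update,
    isotropic_D,
    shell_membrane_stiffness,
    solve_static,
    tet4_stiffness,
)

from conftest import make_bar, make_stacked_blocks, pressure_load, tip_load


REF_TET = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])


class TestTet4:
    def test_symmetric_psd_with_six_rigid_modes(self):
        K = tet4_stiffness(REF_TET, E=1000.0, nu=0.4)
        assert np.abs(K - K.T).max() <= 1e-12 * np.abs(K).max()
        w = np.linalg.eigvalsh(K)
        assert (np.abs(w) < 1e-8 * w.max()).sum() == 6
        assert w.min() > -1e-8 * w.max()

    def test_rigid_motion_produces_no_force(self):
        K = tet4_stiffness(REF_TET, E=500.0, nu=0.3)
        # translation plus a small rotation
        t = np.tile([0.3, -0.7, 1.1], 4)
        omega = np.array([0.01, -0.02, 0.005])
        rot = np.concatenate([np.cross(omega, p) for p in REF_TET])
        for u in (t, rot):
            assert np.abs(K @ u).max() < 1e-9 * np.abs(K).max()

    def test_degenerate_element_is_an_error(self):
        flat = REF_TET.copy()
        flat[3] = [0.5, 0.5, 0.0]
        with pytest.raises(SolverError, match="degenerate"):
            tet4_stiffness(flat, E=1000.0, nu=0.4)

    def test_uniaxial_strain_matches_hookes_law(self):
        """A unit-cube assembly under uniaxial strain reproduces the isotropic
        stiffness column exactly (constant-strain elements are exact)."""
        E, nu = 2000.0, 0.4
        pts, tets = box_mesh(grid_lines(0, 1, 0.5), grid_lines(0, 1, 0.5), grid_lines(0, 1, 0.5))
        mesh = Mesh(points=pts, tets=tets, tet_part=np.full(len(tets), "b", dtype=object))
        mats = MaterialField(
            rho=np.zeros(len(tets)), E=np.full(len(tets), E), nu=np.full(len(tets), nu), part=mesh.tet_part
        )
        eps = 1e-3
        bcs = BoundaryConditions()
        for n, p in enumerate(pts):  # prescribe u = (eps·x, 0, 0) everywhere
            bcs.prescribe(n, np.array([eps * p[0], 0.0, 0.0]))
        res = solve_static(KneeModel(mesh=mesh), mats, bcs, loads=np.zeros((len(pts), 3)))
        D = isotropic_D(E, nu)
        expect = D @ np.array([eps, 0, 0, 0, 0, 0])
        assert np.allclose(res.tet_stress[:, 0, 0], expect[0], rtol=1e-9)
        assert np.allclose(res.tet_stress[:, 1, 1], expect[1], rtol=1e-9)
        assert np.allclose(res.tet_stress[:, 2, 2], expect[2], rtol=1e-9)
        assert np.allclose(res.tet_stress[:, 0, 1], 0.0, atol=1e-9)


class TestShellMembrane:
    TRI = np.array([[0.0, 0, 0], [2, 0, 0], [0, 1, 0]])

    def test_thickness_scales_linearly(self):
        K1 = shell_membrane_stiffness(self.TRI, thickness=1.0)
        K2 = shell_membrane_stiffness(self.TRI, thickness=2.0)
        assert np.allclose(K2, 2 * K1)

    def test_zero_area_is_an_error(self):
        bad = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(SolverError, match="zero-area"):
            shell_membrane_stiffness(bad)

    def test_rigid_modes_have_zero_energy(self):
        K = shell_membrane_stiffness(self.TRI)
        t = np.tile([1.0, -2.0, 0.5], 3)
        assert np.abs(K @ t).max() < 1e-9 * np.abs(K).max()

    def test_in_plane_patch_test(self):
        """Uniform membrane strain is reproduced on a meshed flat square."""
        xs = grid_lines(0, 4, 1.0)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
        n = len(xs)
        tris = []
        for i in range(n - 1):
            for j in range(n - 1):
                a, b, c, d = i * n + j, (i + 1) * n + j, (i + 1) * n + j + 1, i * n + j + 1
                tris += [[a, b, c], [a, c, d]]
        tris = np.array(tris)
        mesh = Mesh(points=pts, tris=tris, tri_part=np.full(len(tris), "patella", dtype=object))
        mats = MaterialField(rho=np.zeros(0), E=np.zeros(0), nu=np.zeros(0), part=np.array([], dtype=object))
        exx, eyy, gxy = 1e-3, -5e-4, 2e-4
        target = np.column_stack(
            [exx * pts[:, 0] + 0.5 * gxy * pts[:, 1], eyy * pts[:, 1] + 0.5 * gxy * pts[:, 0], np.zeros(len(pts))]
        )
        bcs = BoundaryConditions()
        boundary = np.where(
            (pts[:, 0] < 1e-9) | (pts[:, 0] > 4 - 1e-9) | (pts[:, 1] < 1e-9) | (pts[:, 1] > 4 - 1e-9)
        )[0]
        for nid in boundary:
            bcs.prescribe(nid, target[nid])
        bcs.fix_nodes(np.arange(len(pts)), axes=(2,))  # membranes have no z stiffness
        res = solve_static(KneeModel(mesh=mesh), mats, bcs, loads=np.zeros((len(pts), 3)))
        assert np.allclose(res.u, target, atol=1e-10)


class TestSolveStatic:
    def test_zero_loads_zero_solution(self):
        model, mats, bcs = make_bar(res=2.0)
        res = solve_static(model, mats, bcs, loads=np.zeros((model.mesh.n_nodes, 3)))
        assert np.allclose(res.u, 0.0)
        assert np.allclose(res.reactions, 0.0)

    def test_patch_test_linear_field_reproduced(self):
        """Any prescribed linear displacement field is reproduced exactly."""
        pts, tets = box_mesh(grid_lines(0, 3, 1.0), grid_lines(0, 3, 1.0), grid_lines(0, 3, 1.0))
        mesh = Mesh(points=pts, tets=tets, tet_part=np.full(len(tets), "b", dtype=object))
        mats = MaterialField(
            rho=np.zeros(len(tets)), E=np.full(len(tets), 750.0), nu=np.full(len(tets), 0.4), part=mesh.tet_part
        )
        A = np.array([[2.0, 1.0, -0.5], [0.3, -1.2, 0.8], [0.1, 0.4, 1.5]]) * 1e-3
        c = np.array([0.2, -0.1, 0.05]) * 1e-3
        target = pts @ A.T + c
        on_boundary = np.any((pts < 1e-9) | (pts > 3 - 1e-9), axis=1)
        bcs = BoundaryConditions()
        for nid in np.where(on_boundary)[0]:
            bcs.prescribe(nid, target[nid])
        res = solve_static(KneeModel(mesh=mesh), mats, bcs, loads=np.zeros((len(pts), 3)))
        assert np.max(np.abs(res.u - target)) < 1e-12
        # uniform strain -> uniform stress across all elements
        assert np.max(np.std(res.tet_stress, axis=0)) < 1e-9

    def test_bar_tip_displacement_matches_FL_over_EA(self):
        L, E, A, F = 10.0, 1000.0, 4.0, 100.0
        model, mats, bcs = make_bar(length=L, E=E)
        res = solve_static(model, mats, bcs, loads=tip_load(model, F))
        tip = res.u[model.mesh.points[:, 0] > L - 1e-9, 0]
        assert np.allclose(tip, F * L / (E * A), rtol=1e-6)
        assert res.equilibrium_residual() <= 1e-6

    def test_dense_and_sparse_paths_agree(self):
        model, mats, bcs = make_bar(length=4.0, width=2.0, res=2.0)  # 54 DOFs
        assert model.mesh.n_nodes * 3 <= 300
        f = tip_load(model, 37.0)
        u_sparse = solve_static(model, mats, bcs, loads=f, method="sparse").u
        u_dense = solve_static(model, mats, bcs, loads=f, method="dense").u
        scale = np.abs(u_dense).max()
        assert np.max(np.abs(u_sparse - u_dense)) <= 1e-9 * scale

    def test_under_constrained_system_is_an_error(self):
        model, mats, _ = make_bar(res=2.0)
        bcs = BoundaryConditions()
        bcs.fix_nodes(np.array([0]), axes=(0,))
        with pytest.raises(SolverError, match="under-constrained"):
            solve_static(
                model, mats, bcs, loads=tip_load(model, 1.0), stabilization=0.0, step_limit=0.0
            )

    def test_refinement_converges_monotonically_on_bending(self):
        """Transverse tip load: tet4 is too stiff and softens monotonically
        toward the beam solution under refinement."""
        L, E, F = 10.0, 1000.0, 5.0
        tips = []
        for res in (2.0, 1.0, 0.5):
            model, mats, bcs = make_bar(length=L, res=res, E=E, nu=0.0)
            mesh = model.mesh
            bcs = BoundaryConditions()
            bcs.fix_nodes(np.where(mesh.points[:, 0] < 1e-9)[0], axes=(0, 1, 2))
            f = np.zeros((mesh.n_nodes, 3))
            tipn = np.where(mesh.points[:, 0] > L - 1e-9)[0]
            f[tipn, 2] = F / len(tipn)
            r = solve_static(model, mats, bcs, loads=f)
            tips.append(r.u[tipn, 2].mean())
        euler = F * L**3 / (3 * E * (2 * 2**3 / 12))
        assert tips[0] < tips[1] < tips[2] < euler


class TestTensionOnlyTrusses:
    def _two_bar_model(self):
        """A bar with two trusses along x at its tip: one gets stretched, the
        mirrored one goes slack."""
        model, mats, bcs = make_bar(length=6.0, res=2.0)
        mesh = model.mesh
        tipn = int(np.where(
            (mesh.points[:, 0] > 6 - 1e-9) & (mesh.points[:, 1] < 1e-9) & (mesh.points[:, 2] < 1e-9)
        )[0][0])
        behind = len(mesh.points)
        ahead = behind + 1
        mesh.points = np.vstack([mesh.points, [-4.0, 0, 0], [16.0, 0, 0]])
        # pulling the tip in +x stretches the truss anchored behind it and
        # slackens the one anchored ahead of it
        mesh.trusses = np.array([[tipn, behind], [tipn, ahead]])
        mesh.truss_names = ["stretched", "slack"]
        law = TrussLaw("linear", [(0.0, 0.0)], final_slope=5000.0)
        model.truss_laws = {"stretched": law, "slack": law}
        bcs.fix_nodes(np.array([behind, ahead]), axes=(0, 1, 2))
        return model, mats, bcs, tipn

    def test_no_negative_tension_and_slack_removal_is_neutral(self):
        model, mats, bcs, tipn = self._two_bar_model()
        f = tip_load(model, 80.0)
        res = solve_static(model, mats, bcs, loads=f)
        assert np.all(res.truss_tension >= 0)
        names = model.mesh.truss_names
        assert res.truss_tension[names.index("stretched")] > 0
        assert res.truss_tension[names.index("slack")] == 0
        # removing the slack truss changes nothing
        model2, mats2, bcs2, _ = self._two_bar_model()
        model2.mesh.trusses = model2.mesh.trusses[:1]
        model2.mesh.truss_names = ["stretched"]
        res2 = solve_static(model2, mats2, bcs2, loads=tip_load(model2, 80.0))
        assert np.allclose(res2.u, res.u[: len(res2.u)], atol=1e-12)

    def test_truss_tension_follows_its_law(self):
        model, mats, bcs, tipn = self._two_bar_model()
        res = solve_static(model, mats, bcs, loads=tip_load(model, 80.0))
        i = model.mesh.truss_names.index("stretched")
        law = model.truss_laws["stretched"]
        assert res.truss_tension[i] == pytest.approx(law.tension(res.truss_strain[i]))


class TestContact:
    def test_open_gap_no_forces(self):
        model, mats, _ = make_stacked_blocks(gap=1.0)
        states = contact_update(model, mats, np.zeros((model.mesh.n_nodes, 3)))
        assert not states[0].active.any()
        assert np.allclose(states[0].normal_force, 0)
        assert np.allclose(states[0].tangential_force, 0)

    def test_frictionless_pair_has_zero_tangential_traction(self):
        model, mats, bcs = make_stacked_blocks(friction=0.0, nu=0.0)
        res = solve_static(model, mats, bcs, loads=pressure_load(model, 2.0))
        st = res.contact[0]
        assert np.allclose(st.tangential_force, 0.0)
        assert st.active.sum() > 0

    def test_stacked_blocks_transmit_applied_pressure(self):
        p = 2.0
        model, mats, bcs = make_stacked_blocks()
        res = solve_static(model, mats, bcs, loads=pressure_load(model, p))
        st = res.contact[0]
        total = st.normal_force.sum(axis=0)[2]
        assert total == pytest.approx(p * 100.0, rel=0.005)
        assert res.equilibrium_residual() <= 1e-6

    def test_coulomb_cap_and_compression_only(self):
        model, mats, bcs = make_stacked_blocks(friction=0.01)
        res = solve_static(model, mats, bcs, loads=pressure_load(model, 2.0))
        st = res.contact[0]
        fn = np.linalg.norm(st.normal_force, axis=1)
        ft = np.linalg.norm(st.tangential_force, axis=1)
        active = fn > 0
        assert np.all(ft[active] <= 0.01 * fn[active] * (1 + 1e-9))
        # compression only: normal forces push the slave away from the master
        push = np.einsum("ij,ij->i", st.normal_force[active], st.normal[active])
        assert np.all(push >= 0)
        assert np.all(fn[~st.active] == 0)
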