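"""Truss laws, pose transform, constraints, forced-displacement actuation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kneefem.model import (
    KneeModel,
    PosePrescription,
    TrussLaw,
    apply_pose,
    build_constraints,
    calibrate_forced_displacement,
    compose_joint_rotation,
    cruciate_collateral_law,
    decompose_joint_rotation,
    eval_truss_tension,
    patellar_tendon_law,
)


class TestTrussLaw:
    def test_tendon_plateau_and_ramp(self):
        law = patellar_tendon_law()
        assert eval_truss_tension(law, 0.01) == 863.77
        assert eval_truss_tension(law, 0.0025) == pytest.approx(431.885)
        assert eval_truss_tension(law, -0.1) == 0.0
        assert eval_truss_tension(law, 0.005) == 863.77

    def test_tendon_ramp_meets_plateau_exactly(self):
        # the printed ramp slope times the knee strain equals the plateau
        assert 172754 * 0.005 == 863.77

    def test_ligament_ramp(self):
        law = cruciate_collateral_law()
        assert eval_truss_tension(law, -0.05) == 0.0
        assert eval_truss_tension(law, 0.02) == pytest.approx(20.0)

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(min_value=-0.2, max_value=0.2),
        st.floats(min_value=-0.2, max_value=0.2),
    )
    def test_tension_only_and_monotone(self, e1, e2):
        for law in (patellar_tendon_law(), cruciate_collateral_law()):
            t1, t2 = law.tension(e1), law.tension(e2)
            assert t1 >= 0 and t2 >= 0
            if e1 <= 0:
                assert t1 == 0
            if e1 <= e2:
                assert t1 <= t2

    def test_breakpoint_validation(self):
        with pytest.raises(ValueError):
            TrussLaw("bad", [(0.0, 0.0), (0.01, 5.0), (0.005, 10.0)])
        with pytest.raises(ValueError):
            TrussLaw("bad", [(0.0, 0.0), (0.01, 5.0)], final_slope=-1.0)

    def test_law_serialization_round_trip(self):
        law = patellar_tendon_law()
        clone = TrussLaw.from_dict(law.to_dict())
        assert clone.breakpoints == law.breakpoints
        assert clone.tension(0.0037) == law.tension(0.0037)


class TestPose:
    def test_zero_angles_is_identity(self, knee_model):
        pose = PosePrescription(knee_inversion=0, knee_bending=0, knee_inward=0)
        posed = apply_pose(knee_model, pose, reseat_clearance=None)
        assert np.allclose(posed.mesh.points, knee_model.mesh.points)

    def test_rotation_is_proper(self):
        R = PosePrescription().rotation().as_matrix()
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_lr_angles_round_trip(self):
        R = compose_joint_rotation(14.62, 12.21, -3.28)
        bending, inversion, inward = decompose_joint_rotation(R)
        assert bending == pytest.approx(14.62, abs=1e-6)
        assert inversion == pytest.approx(12.21, abs=1e-6)
        assert inward == pytest.approx(-3.28, abs=1e-6)

    def test_pose_preserves_intra_part_distances(self, knee_model):
        posed = apply_pose(knee_model, PosePrescription())
        rng = np.random.default_rng(0)
        femur = knee_model.mesh.part_nodes("femur")
        pick = rng.choice(femur, size=40, replace=False)
        before = np.linalg.norm(
            knee_model.mesh.points[pick][:, None] - knee_model.mesh.points[pick][None], axis=-1
        )
        after = np.linalg.norm(
            posed.mesh.points[pick][:, None] - posed.mesh.points[pick][None], axis=-1
        )
        assert np.allclose(after, before, rtol=1e-9, atol=1e-9)
        # tibia untouched
        tibia = knee_model.mesh.part_nodes("tibia")
        assert np.array_equal(posed.mesh.points[tibia], knee_model.mesh.points[tibia])

    def test_reseat_leaves_prescribed_clearance(self, knee_model):
        posed = apply_pose(knee_model, PosePrescription(), reseat_clearance=0.1)
        inf = posed.mesh.points[posed.mesh.node_sets["femur_inferior_nodes"]]
        tops = [
            posed.mesh.points[posed.mesh.node_sets[k]][:, 2].max()
            for k in ("meniscus_superior_nodes", "cartilage_superior_nodes")
        ]
        assert inf[:, 2].min() == pytest.approx(max(tops) + 0.1)

    def test_missing_part_is_an_error(self, knee_model):
        mesh = knee_model.mesh
        mesh2 = type(mesh)(
            points=mesh.points,
            tets=mesh.tets,
            tet_part=np.full(len(mesh.tets), "tibia", dtype=object),
        )
        with pytest.raises(ValueError, match="femur"):
            apply_pose(knee_model.replace(mesh=mesh2), PosePrescription())


class TestConstraints:
    def test_femur_fixed_tibia_xy_only(self, knee_model):
        bcs = build_constraints(knee_model)
        mesh = knee_model.mesh
        fixed_by_node = {}
        for dof in bcs.fixed:
            fixed_by_node.setdefault(dof // 3, set()).add(dof % 3)
        for n in mesh.node_sets["femur_proximal_nodes"]:
            assert fixed_by_node[int(n)] == {0, 1, 2}
        for n in mesh.node_sets["tibia_distal_nodes"]:
            assert fixed_by_node[int(n)] == {0, 1}
        allowed = set(mesh.node_sets["femur_proximal_nodes"]) | set(
            mesh.node_sets["tibia_distal_nodes"]
        )
        assert set(fixed_by_node) == {int(n) for n in allowed}

    def test_empty_node_set_is_an_error(self, knee_model):
        broken = knee_model.replace(mesh=knee_model.mesh)
        sets = dict(broken.mesh.node_sets)
        sets["femur_proximal_nodes"] = np.array([], dtype=int)
        broken.mesh.node_sets = sets
        with pytest.raises(ValueError, match="empty"):
            build_constraints(broken)
        broken.mesh.node_sets = {
            k: v for k, v in sets.items() if k != "femur_proximal_nodes"
        }
        with pytest.raises(ValueError, match="missing"):
            build_constraints(broken)


class TestForcedDisplacement:
    def test_plateau_target_achieved(self, knee_model):
        act = calibrate_forced_displacement(knee_model, target_traction=863.77, displacement=3.0)
        assert act["tension"] == 863.77
        assert act["strain"] > 0.005
        assert np.linalg.norm(act["vector"]) == pytest.approx(3.0)

    def test_zero_target_is_noop(self, knee_model):
        act = calibrate_forced_displacement(knee_model, target_traction=0.0)
        assert act["tension"] == 0.0
        assert act["node"] is None

    def test_below_plateau_warns_with_ramp_tension(self, knee_model):
        # shrink displacement so the strain stays on the ramp
        idx = knee_model.mesh.truss_names.index("quadriceps")
        n0, n1 = knee_model.mesh.trusses[idx]
        L0 = np.linalg.norm(knee_model.mesh.points[n1] - knee_model.mesh.points[n0])
        d = 0.5 * 0.005 * L0
        with pytest.warns(UserWarning, match="below the"):
            act = calibrate_forced_displacement(knee_model, displacement=d)
        assert act["tension"] == pytest.approx(172754 * act["strain"])
        assert act["tension"] < 863.77


def test_model_serialization_round_trip(knee_model, tmp_path):
    path = tmp_path / "model.json"
    knee_model.save_json(path)
    clone = KneeModel.load_json(path)
    assert np.array_equal(clone.mesh.points, knee_model.mesh.points)
    assert clone.load_case == knee_model.load_case
    assert [p.to_dict() for p in clone.contact_pairs] == [
        p.to_dict() for p in knee_model.contact_pairs
    ]
    assert set(clone.truss_laws) == set(knee_model.truss_laws)
    # bit-exact rewrite
    path2 = tmp_path / "model2.json"
    clone.save_json(path2)
    assert path.read_text() == path2.read_text()
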