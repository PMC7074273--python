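"""Generators: CT phantom ground truth, knee mesh quality, gait fixture."""

import numpy as np
import pytest

from kneefem.materials import calibrate_hu_density
from kneefem.synthetic import (
    BoneBody,
    GaitFixtureSpec,
    PhantomSpec,
    SOFT_TISSUE_HU,
    AIR_HU,
    make_ct_phantom,
    make_gait_fixture,
    make_knee_mesh,
    rod_masks,
    rod_samples,
)


class TestPhantom:
    def test_rod_hu_inverts_calibration_exactly(self, phantom_default):
        spec, vol, density = phantom_default
        a, b = spec.true_calibration
        for mask, rho in zip(rod_masks(spec, vol), spec.rod_densities):
            assert np.allclose(vol.data[mask], (rho - b) / a)
            assert np.allclose(density[mask], rho)

    def test_recovered_calibration_matches_truth(self, phantom_default):
        spec, vol, _ = phantom_default
        cal = calibrate_hu_density(rod_samples(spec, vol))
        a, b = spec.true_calibration
        assert abs(cal.a - a) <= 1e-9 * abs(a)
        assert abs(cal.b - b) <= 1e-9 * max(abs(b), 1.0)

    def test_background_and_air_values(self, phantom_default):
        spec, vol, _ = phantom_default
        assert vol.data[0, 0, 0] == AIR_HU
        # a voxel away from bones, rods and border is soft tissue
        centre = vol.world_to_voxel(np.array([[0.0, 20.0, 36.0]]))[0].round().astype(int)
        assert vol.data[tuple(centre)] == SOFT_TISSUE_HU

    def test_same_seed_identical_volumes(self):
        s1 = PhantomSpec(noise_sd=10.0, seed=7)
        s2 = PhantomSpec(noise_sd=10.0, seed=7)
        v1, d1 = make_ct_phantom(s1)
        v2, d2 = make_ct_phantom(s2)
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(d1, d2)
        v3, _ = make_ct_phantom(PhantomSpec(noise_sd=10.0, seed=8))
        assert not np.array_equal(v1.data, v3.data)

    def test_out_of_bounds_body_names_offender(self):
        spec = PhantomSpec(
            bone_geometry=[BoneBody("runaway", lo=(-18, -12, -30), hi=(18, 12, 500))]
        )
        with pytest.raises(ValueError, match="runaway"):
            make_ct_phantom(spec)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(spacing=(0, 1, 1))
        with pytest.raises(ValueError):
            PhantomSpec(rod_densities=(-0.1, 0.5))


class TestKneeMesh:
    def test_positive_volumes_finite_coords(self, knee_model):
        mesh = knee_model.mesh
        assert mesh.tet_volumes().min() > 0
        assert np.all(np.isfinite(mesh.points))

    def test_all_part_labels_present(self, knee_model):
        mesh = knee_model.mesh
        assert set(mesh.tet_part) == {"femur", "tibia", "cartilage", "meniscus"}
        assert set(mesh.tri_part) == {"patella"}
        assert len(mesh.trusses) == 6
        assert set(mesh.truss_names) == {
            "quadriceps", "patellar_ligament", "mcl", "lcl", "acl", "pcl",
        }

    def test_parts_are_disjoint(self, knee_model):
        mesh = knee_model.mesh
        seen = {}
        for part in ("femur", "tibia", "cartilage", "meniscus"):
            ids = set(map(tuple, np.sort(mesh.tets[mesh.tet_part == part], axis=1)))
            for other, prev in seen.items():
                assert not (ids & prev), f"{part} shares elements with {other}"
            seen[part] = ids

    def test_shells_cover_patellar_patch(self, knee_model):
        mesh = knee_model.mesh
        patch = mesh.node_sets["patella_patch_nodes"]
        assert set(mesh.tris.ravel()) == set(patch.tolist())
        # the patch sits on the femur anterior surface
        assert np.all(mesh.points[patch, 1] == mesh.points[patch, 1].max())

    def test_element_count_scales_with_resolution(self):
        n2 = len(make_knee_mesh(2.0).mesh.tets)
        n1 = len(make_knee_mesh(1.0).mesh.tets)
        assert 4.0 <= n1 / n2 <= 12.0  # ~8× with ±50% slack

    def test_resolution_validation(self):
        with pytest.raises(ValueError):
            make_knee_mesh(0.2)
        with pytest.raises(ValueError):
            make_knee_mesh(6.0)

    def test_generated_mesh_passes_patch_test(self):
        """A linear displacement field prescribed on every part boundary is
        reproduced in the interior of the generated (crowned, multi-part)
        mesh — uniform-strain completeness of the tet discretisation."""
        from kneefem.materials import MaterialField
        from kneefem.mesh import boundary_faces
        from kneefem.model import BoundaryConditions, KneeModel
        from kneefem.solver import solve_static

        mesh = make_knee_mesh(4.0).mesh
        tets_only = type(mesh)(points=mesh.points, tets=mesh.tets, tet_part=mesh.tet_part)
        mats = MaterialField(
            rho=np.zeros(len(mesh.tets)),
            E=np.full(len(mesh.tets), 1000.0),
            nu=np.full(len(mesh.tets), 0.4),
            part=mesh.tet_part,
        )
        A = np.array([[0.9, 0.2, -0.3], [0.1, -1.1, 0.4], [-0.2, 0.3, 1.2]]) * 1e-3
        target = mesh.points @ A.T
        bcs = BoundaryConditions()
        bnodes = np.unique(boundary_faces(mesh.tets).ravel())
        for nid in bnodes:
            bcs.prescribe(int(nid), target[nid])
        # the quadriceps anchor is not part of any tet; pin it too
        loose = np.setdiff1d(np.arange(mesh.n_nodes), np.unique(mesh.tets.ravel()))
        for nid in loose:
            bcs.prescribe(int(nid), target[nid])
        res = solve_static(
            KneeModel(mesh=tets_only), mats, bcs, loads=np.zeros((mesh.n_nodes, 3))
        )
        assert np.max(np.abs(res.u - target)) < 1e-10


@pytest.fixture(scope="module")
def rec():
    return make_gait_fixture(GaitFixtureSpec(seed=3))


class TestGaitFixture:
    def test_grf_support_interval_matches_stance(self, rec):
        spec = GaitFixtureSpec(seed=3)
        t = rec.grf["time"].to_numpy()
        fz = rec.grf["fz"].to_numpy()
        on = t[fz > 0]
        assert on.max() - on.min() == pytest.approx(
            spec.stance_duration, abs=2.0 / spec.grf_rate
        )
        assert np.all(fz >= 0)

    def test_grf_peak_equals_prescribed_upward_force(self, rec):
        assert rec.grf["fz"].max() == pytest.approx(808.95, rel=0.01)

    def test_streams_and_channels_present(self, rec):
        for name in ("RASI", "RPSI", "RTHI", "RKNE", "RTIB", "RANK", "RHEE", "RTOE"):
            assert f"{name}_x" in rec.markers.columns
        for ch in ("RF", "VM", "VL", "BF", "ST"):
            assert ch in rec.emg.columns

    def test_fixed_seed_reproduces_streams(self):
        a = make_gait_fixture(GaitFixtureSpec(seed=11, marker_noise_sd=1.0))
        b = make_gait_fixture(GaitFixtureSpec(seed=11, marker_noise_sd=1.0))
        assert a.emg.equals(b.emg)
        assert a.markers.equals(b.markers)
        assert a.grf.equals(b.grf)

    def test_csv_round_trip(self, rec, tmp_path):
        rec.save_csv(tmp_path / "gait")
        from kneefem.gait import GaitRecording

        back = GaitRecording.load_csv(tmp_path / "gait")
        assert np.allclose(back.grf["fz"], rec.grf["fz"])
        assert back.meta["grf_peak"] == rec.meta["grf_peak"]

    def test_burst_centre_validation(self):
        with pytest.raises(ValueError):
            GaitFixtureSpec(emg_burst_centers={"RF": 1.5})
        with pytest.raises(ValueError):
            GaitFixtureSpec(stance_duration=-1.0)
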