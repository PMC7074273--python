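"""Shared fixtures: small meshes, phantoms, and the solved synthetic knee."""

from __future__ import annotations

import numpy as np
import pytest

from kneefem.mesh import Mesh, box_mesh, grid_lines, boundary_faces, merge_meshes
from kneefem.materials import MaterialField
from kneefem.model import KneeModel, BoundaryConditions, ContactPair
from kneefem.synthetic import PhantomSpec, make_ct_phantom, make_knee_mesh


def make_bar(length=10.0, width=2.0, res=1.0, E=1000.0, nu=0.4):
    """Uniaxial bar: x=0 face supported so a uniform axial stress state is
    admissible (Poisson contraction free), unit tip traction helpers."""
    pts, tets = box_mesh(grid_lines(0, length, res), grid_lines(0, width, res), grid_lines(0, width, res))
    mesh = Mesh(points=pts, tets=tets, tet_part=np.full(len(tets), "bar", dtype=object))
    faces = boundary_faces(tets)
    cent = pts[faces].mean(axis=1)
    mesh.facet_sets["tip_facets"] = faces[cent[:, 0] > length - 1e-9]
    mats = MaterialField(
        rho=np.zeros(len(tets)), E=np.full(len(tets), E), nu=np.full(len(tets), nu), part=mesh.tet_part
    )
    bcs = BoundaryConditions()
    bcs.fix_nodes(np.where(pts[:, 0] < 1e-9)[0], axes=(0,))
    corner = lambda x, y, z: np.where(
        (np.abs(pts[:, 0] - x) < 1e-9) & (np.abs(pts[:, 1] - y) < 1e-9) & (np.abs(pts[:, 2] - z) < 1e-9)
    )[0]
    bcs.fix_nodes(corner(0, 0, 0), axes=(1, 2))
    bcs.fix_nodes(corner(0, width, 0), axes=(2,))
    return KneeModel(mesh=mesh), mats, bcs


def tip_load(model, total_force):
    """Area-weighted nodal forces for a uniform axial traction on the tip."""
    mesh = model.mesh
    faces = mesh.facet_sets["tip_facets"]
    areas = mesh.tri_areas(faces)
    f = np.zeros((mesh.n_nodes, 3))
    A = areas.sum()
    for tri, a in zip(faces, areas):
        for n in tri:
            f[n, 0] += total_force * (a / A) / 3.0
    return f


def make_stacked_blocks(gap=0.05, friction=0.01, E=100.0, nu=0.3, support="top"):
    """Two 10×10 blocks with a contact interface; pressure applied on top.

    ``support`` picks where the upper block is held laterally: "top" (load
    face) leaves the contact surface free to slide under friction, "bottom"
    pins it.
    """
    p_lo, t_lo = box_mesh(grid_lines(0, 10, 2.0), grid_lines(0, 10, 2.0), grid_lines(0, 5, 2.5))
    p_hi, t_hi = box_mesh(
        grid_lines(0, 10, 2.0), grid_lines(0, 10, 2.0), grid_lines(5 + gap, 10 + gap, 2.5)
    )
    pts, tets, part, _ = merge_meshes([(p_lo, t_lo, "lower"), (p_hi, t_hi, "upper")])
    mesh = Mesh(points=pts, tets=tets, tet_part=part)

    def surf(mask, pred, name):
        faces = boundary_faces(tets[mask])
        p0, p1, p2 = pts[faces[:, 0]], pts[faces[:, 1]], pts[faces[:, 2]]
        n = np.cross(p1 - p0, p2 - p0)
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        c = (p0 + p1 + p2) / 3
        sel = pred(c, n)
        mesh.facet_sets[name + "_facets"] = faces[sel]
        mesh.node_sets[name + "_nodes"] = np.unique(faces[sel].ravel())

    surf(part == "lower", lambda c, n: n[:, 2] > 0.7, "lower_top")
    surf(part == "upper", lambda c, n: n[:, 2] < -0.7, "upper_bottom")
    surf(part == "upper", lambda c, n: n[:, 2] > 0.7, "upper_top")
    mats = MaterialField(
        rho=np.zeros(len(tets)), E=np.full(len(tets), E), nu=np.full(len(tets), nu), part=part
    )
    bcs = BoundaryConditions()
    bcs.fix_nodes(np.where(pts[:, 2] < 1e-9)[0], axes=(0, 1, 2))
    lateral = "upper_top_nodes" if support == "top" else "upper_bottom_nodes"
    bcs.fix_nodes(mesh.node_sets[lateral], axes=(0, 1))
    model = KneeModel(
        mesh=mesh,
        contact_pairs=[ContactPair("upper_bottom_nodes", "lower_top_facets", friction=friction)],
    )
    return model, mats, bcs


def pressure_load(model, pressure, facet_set="upper_top_facets", axis=2, sign=-1):
    mesh = model.mesh
    faces = mesh.facet_sets[facet_set]
    areas = mesh.tri_areas(faces)
    f = np.zeros((mesh.n_nodes, 3))
    for tri, a in zip(faces, areas):
        for n in tri:
            f[n, axis] += sign * pressure * a / 3.0
    return f


@pytest.fixture(scope="session")
def phantom_default():
    spec = PhantomSpec()
    vol, density = make_ct_phantom(spec)
    return spec, vol, density


@pytest.fixture(scope="session")
def knee_model():
    return make_knee_mesh(3.0)


@pytest.fixture(scope="session")
def solved_knee(phantom_default):
    """End-to-end solved synthetic knee under the LR-phase pose and loads."""
    from kneefem.materials import calibrate_hu_density, assign_element_materials
    from kneefem.model import (
        PosePrescription,
        apply_pose,
        build_constraints,
        calibrate_forced_displacement,
        build_external_forces,
    )
    from kneefem.solver import solve_static
    from kneefem.synthetic import rod_samples

    spec, vol, _ = phantom_default
    cal = calibrate_hu_density(rod_samples(spec, vol))
    model = make_knee_mesh(3.0)
    mats = assign_element_materials(model.mesh, vol, cal)
    posed = apply_pose(model, PosePrescription())
    bcs = build_constraints(posed)
    act = calibrate_forced_displacement(posed)
    bcs.prescribe(act["node"], act["vector"])
    loads = build_external_forces(posed)
    result = solve_static(posed, mats, bcs, loads=loads, max_iter=200)
    return posed, mats, bcs, loads, result
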