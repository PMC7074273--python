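"""Boundary-value-problem assembly for the posed knee.

Coordinate convention: X medial–lateral (medial = +X for the modelled right
knee), Y anterior–posterior, Z vertical (floor normal). Units mm–N–MPa.

The knee is posed at the load-response (LR) phase of stance by rigidly
rotating the femur relative to the tibia through the three clinical angles
(flexion/"bending", varus/"inversion", internal/"inward" rotation). Ligaments
and tendons are 2-node truss elements that carry tension only, with
piecewise-linear strain–tension laws; the quadriceps is actuated by a
prescribed 3-mm displacement calibrated so that the truss operates on the
plateau of its law and therefore transmits exactly the target traction.
Only the vertical ground-reaction component is applied in the solve; the
horizontal components are carried in the data model but excluded by default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from kneefem.mesh import Mesh


# ------------------------------------------------------------------ trusses

@dataclass
class TrussLaw:
    """Tension-only piecewise-linear strain–tension law.

    ``breakpoints`` is a list of (strain, tension N) pairs with strictly
    increasing strain, starting at (0, 0). Tension is 0 for strain ≤ 0,
    linearly interpolated between breakpoints, and continues beyond the last
    breakpoint with slope ``final_slope`` (default 0, i.e. a plateau).
    """

    name: str
    breakpoints: list
    final_slope: float = 0.0

    def __post_init__(self) -> None:
        bp = [(float(e), float(t)) for e, t in self.breakpoints]
        if not bp or bp[0] != (0.0, 0.0):
            bp = [(0.0, 0.0)] + [p for p in bp if p != (0.0, 0.0)]
        eps = [e for e, _ in bp]
        tns = [t for _, t in bp]
        if any(e2 <= e1 for e1, e2 in zip(eps, eps[1:])):
            raise ValueError("truss-law breakpoint strains must be strictly increasing")
        if any(t2 < t1 for t1, t2 in zip(tns, tns[1:])) or self.final_slope < 0:
            raise ValueError("truss-law tension must be non-decreasing")
        self.breakpoints = bp

    def tension(self, strain) -> np.ndarray | float:
        """Tension (N) at the given strain; 0 for any strain ≤ 0."""
        e = np.asarray(strain, dtype=float)
        eps = np.array([p[0] for p in self.breakpoints])
        tns = np.array([p[1] for p in self.breakpoints])
        t = np.interp(e, eps, tns)
        beyond = e > eps[-1]
        t = np.where(beyond, tns[-1] + self.final_slope * (e - eps[-1]), t)
        t = np.where(e <= 0, 0.0, t)
        return float(t) if np.isscalar(strain) else t

    def slope(self, strain) -> np.ndarray | float:
        """Local tangent dT/dε (N per unit strain); 0 for strain ≤ 0."""
        e = np.asarray(strain, dtype=float)
        eps = np.array([p[0] for p in self.breakpoints])
        tns = np.array([p[1] for p in self.breakpoints])
        seg_slopes = np.diff(tns) / np.diff(eps) if len(eps) > 1 else np.array([])
        idx = np.clip(np.searchsorted(eps, e, side="right") - 1, 0, max(len(seg_slopes) - 1, 0))
        if len(seg_slopes):
            k = seg_slopes[idx]
            k = np.where(e > eps[-1], self.final_slope, k)
        else:
            k = np.full_like(e, self.final_slope)
        k = np.where(e <= 0, 0.0, k)
        return float(k) if np.isscalar(strain) else k

    def to_dict(self) -> dict:
        return {"name": self.name, "breakpoints": self.breakpoints, "final_slope": self.final_slope}

    @classmethod
    def from_dict(cls, d: dict) -> "TrussLaw":
        return cls(name=d["name"], breakpoints=[tuple(p) for p in d["breakpoints"]], final_slope=d["final_slope"])


def patellar_tendon_law() -> TrussLaw:
    """Patellar ligament / quadriceps tendon: 0 below ε=0, 172754·ε up to
    ε=0.005, then a plateau at 863.77 N (172754 × 0.005 = 863.77 exactly)."""
    return TrussLaw("patellar_tendon", [(0.0, 0.0), (0.005, 863.77)], final_slope=0.0)


def cruciate_collateral_law() -> TrussLaw:
    """Cruciate / collateral ligaments: 0 below ε=0, 1000·ε N above."""
    return TrussLaw("cruciate_collateral", [(0.0, 0.0)], final_slope=1000.0)


def eval_truss_tension(law: TrussLaw, strain: float) -> float:
    """Tension-only piecewise evaluation of a truss law."""
    return law.tension(strain)


# ------------------------------------------------------------------ pose

@dataclass
class PosePrescription:
    """Clinical angles (degrees) defining the LR-phase posture.

    ``knee_*``: femur relative to tibia; ``tibia_*``: tibia relative to the
    floor (recorded for reference; the FE model keeps the tibia vertical and
    poses the femur). Signs: flexion (bending), varus (inversion) and internal
    (inward) rotation positive.
    """

    knee_inversion: float = 12.21
    knee_bending: float = 14.62
    knee_inward: float = -3.28
    tibia_inversion: float = 11.5
    tibia_bending: float = 13.3
    tibia_inward: float = 7.7

    def rotation(self) -> Rotation:
        """Femur-relative-to-tibia rotation.

        Intrinsic sequence flexion (about X, medial–lateral axis) → varus
        (about Y, anterior–posterior axis) → internal rotation (about Z, long
        axis), matching the joint-coordinate-system convention.
        """
        return compose_joint_rotation(self.knee_bending, self.knee_inversion, self.knee_inward)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PosePrescription":
        return cls(**d)


def compose_joint_rotation(bending: float, inversion: float, inward: float) -> Rotation:
    """Intrinsic X (flexion) → Y (varus) → Z (internal) rotation, degrees."""
    return Rotation.from_euler("XYZ", [bending, inversion, inward], degrees=True)


def decompose_joint_rotation(R: Rotation) -> tuple[float, float, float]:
    """Inverse of :func:`compose_joint_rotation` → (bending, inversion, inward) deg."""
    ang = R.as_euler("XYZ", degrees=True)
    return float(ang[0]), float(ang[1]), float(ang[2])


FEMUR_SIDE_SETS = (
    "femur_proximal_nodes",
    "femur_inferior_nodes",
    "patella_patch_nodes",
    "quad_anchor_nodes",
)


def apply_pose(
    model: "KneeModel",
    pose: PosePrescription,
    center: np.ndarray | None = None,
    reseat_clearance: float | None = 0.1,
) -> "KneeModel":
    """Rigidly rotate the femur (and everything attached to it) into the pose.

    The rotation is applied about ``center`` (default: centroid of the femur
    inferior surface). With ``reseat_clearance`` set, the femur is afterwards
    translated vertically so its lowest inferior-surface node clears the
    highest opposing surface node by exactly that many mm — posing is a rigid
    placement, contact closure happens in the solve.
    """
    mesh = model.mesh
    if "femur" not in set(mesh.tet_part.astype(str)):
        raise ValueError("mesh has no part labelled 'femur'")
    femur_nodes = set(mesh.part_nodes("femur").tolist())
    for s in FEMUR_SIDE_SETS:
        if s in mesh.node_sets:
            femur_nodes.update(np.asarray(mesh.node_sets[s]).tolist())
    femur_nodes = np.array(sorted(femur_nodes), dtype=int)

    if center is None:
        inf = mesh.node_sets.get("femur_inferior_nodes", femur_nodes)
        center = mesh.points[inf].mean(axis=0)
    R = pose.rotation().as_matrix()
    pts = mesh.points.copy()
    pts[femur_nodes] = (pts[femur_nodes] - center) @ R.T + center

    if reseat_clearance is not None:
        inf = mesh.node_sets.get("femur_inferior_nodes", femur_nodes)
        opposing = [
            mesh.node_sets[k]
            for k in ("meniscus_superior_nodes", "cartilage_superior_nodes")
            if k in mesh.node_sets
        ]
        if opposing:
            top = max(float(pts[o][:, 2].max()) for o in opposing)
            shift = (top + reseat_clearance) - float(pts[inf][:, 2].min())
            pts[femur_nodes, 2] += shift

    posed = Mesh(
        points=pts,
        tets=mesh.tets.copy(),
        tet_part=mesh.tet_part.copy(),
        tris=mesh.tris.copy(),
        tri_part=mesh.tri_part.copy(),
        trusses=mesh.trusses.copy(),
        truss_names=list(mesh.truss_names),
        node_sets={k: np.asarray(v).copy() for k, v in mesh.node_sets.items()},
        facet_sets={k: np.asarray(v).copy() for k, v in mesh.facet_sets.items()},
    )
    out = model.replace(mesh=posed)
    out.pose = pose
    return out


# ------------------------------------------------------------------ loads/BCs

@dataclass
class LoadCase:
    """Measured ground reaction and computed muscle tractions (N).

    Only the vertical (upward) GRF component enters the solve by default; the
    horizontal components are retained for completeness. The quadriceps is not
    applied as a force — it is actuated by forced displacement (see
    :func:`calibrate_forced_displacement`).
    """

    grf_inward: float = 26.08
    grf_forward: float = -112.00
    grf_upward: float = 808.95
    quadriceps: float = 863.77
    biceps_femoris: float = 266.26
    semimembranosus: float = 99.99
    semitendinosus_gracilis: float = 61.11
    forced_displacement: float = 3.0
    apply_horizontal_grf: bool = False

    def __post_init__(self) -> None:
        for name in ("quadriceps", "biceps_femoris", "semimembranosus", "semitendinosus_gracilis"):
            if getattr(self, name) < 0:
                raise ValueError(f"muscle traction {name} must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LoadCase":
        return cls(**d)


@dataclass
class ContactPair:
    """A slave-node-set / master-facet-set contact definition.

    Non-tied pairs transmit compression only, with Coulomb friction capped at
    μ·|normal| (μ = 0.01 by default). Tied pairs are bonded (tension and
    compression, no sliding) — used for the meniscus inner rim fixed to the
    tibial cartilage.
    """

    slave_nodes: str
    master_facets: str
    friction: float = 0.01
    penalty: float | None = None  # N/mm per slave node; None → auto from materials
    tied: bool = False

    def __post_init__(self) -> None:
        if self.friction < 0:
            raise ValueError("friction coefficient must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ContactPair":
        return cls(**d)


@dataclass
class BoundaryConditions:
    """Prescribed nodal displacement components.

    ``fixed`` maps global DOF index (3·node + axis) to the prescribed value.
    """

    fixed: dict = field(default_factory=dict)

    def fix_nodes(self, nodes: np.ndarray, axes=(0, 1, 2), value: float = 0.0) -> None:
        for n in np.asarray(nodes, dtype=int).ravel():
            for ax in axes:
                self.fixed[3 * int(n) + ax] = float(value)

    def prescribe(self, node: int, vector: np.ndarray) -> None:
        for ax in range(3):
            self.fixed[3 * int(node) + ax] = float(vector[ax])

    @property
    def dofs(self) -> np.ndarray:
        return np.array(sorted(self.fixed), dtype=int)

    @property
    def values(self) -> np.ndarray:
        return np.array([self.fixed[d] for d in sorted(self.fixed)], dtype=float)


def build_constraints(model: "KneeModel") -> BoundaryConditions:
    """Support conditions: proximal femur fully fixed; distal tibia (and
    fibula, when present) fixed in X and Y with Z left free for the vertical
    ground reaction."""
    mesh = model.mesh
    bcs = BoundaryConditions()
    for name, axes in (
        ("femur_proximal_nodes", (0, 1, 2)),
        ("tibia_distal_nodes", (0, 1)),
        ("fibula_distal_nodes", (0, 1)),
    ):
        if name not in mesh.node_sets:
            if name == "fibula_distal_nodes":
                continue
            raise ValueError(f"missing node set {name!r}")
        nodes = np.asarray(mesh.node_sets[name], dtype=int)
        if nodes.size == 0:
            raise ValueError(f"node set {name!r} is empty")
        bcs.fix_nodes(nodes, axes=axes)
    return bcs


def calibrate_forced_displacement(
    model: "KneeModel",
    target_traction: float = 863.77,
    displacement: float = 3.0,
    truss_name: str = "quadriceps",
) -> dict:
    """Calibrate the quadriceps forced-displacement actuation.

    A prescribed ``displacement`` (mm, default 3) applied at the actuation
    anchor stretches the quadriceps truss by strain = displacement / reference
    length. The strain–tension law is defined so that at that strain the truss
    sits on its plateau and transmits exactly ``target_traction``. Returns the
    actuation record (anchor node, displacement vector, achieved tension);
    warns when the displacement cannot reach the plateau.
    """
    if target_traction < 0:
        raise ValueError("target traction must be non-negative")
    if truss_name not in model.mesh.truss_names:
        raise ValueError(f"no truss named {truss_name!r}")
    if target_traction == 0:
        return {"node": None, "vector": np.zeros(3), "strain": 0.0, "tension": 0.0}
    idx = model.mesh.truss_names.index(truss_name)
    n0, n1 = model.mesh.trusses[idx]
    p0, p1 = model.mesh.points[n0], model.mesh.points[n1]
    axis = p1 - p0
    L0 = float(np.linalg.norm(axis))
    axis = axis / L0
    strain = displacement / L0
    law = model.truss_laws[truss_name]
    tension = law.tension(strain)
    plateau_strain = law.breakpoints[-1][0]
    if strain < plateau_strain and law.final_slope == 0.0:
        warnings.warn(
            f"forced displacement {displacement} mm gives strain {strain:.5f} below the "
            f"plateau knee {plateau_strain}; achieved tension {tension:.2f} N "
            f"< target {target_traction:.2f} N"
        )
    # anchor is the far (n1) end; displacement prescribed along the truss axis
    return {"node": int(n1), "vector": displacement * axis, "strain": strain, "tension": float(tension)}


# ------------------------------------------------------------------ model

@dataclass
class KneeModel:
    """Mesh + truss laws + contact pairs + loads + pose, ready for the solver."""

    mesh: Mesh
    truss_laws: dict = field(default_factory=dict)
    contact_pairs: list = field(default_factory=list)
    load_case: LoadCase = field(default_factory=LoadCase)
    pose: PosePrescription | None = None
    shell_props: dict = field(
        default_factory=lambda: {"E": 1000.0, "nu": 0.4, "thickness": 1.0}
    )

    def replace(self, **kw) -> "KneeModel":
        d = {
            "mesh": self.mesh,
            "truss_laws": self.truss_laws,
            "contact_pairs": self.contact_pairs,
            "load_case": self.load_case,
            "pose": self.pose,
            "shell_props": self.shell_props,
        }
        d.update(kw)
        return KneeModel(**d)

    def to_dict(self) -> dict:
        return {
            "mesh": self.mesh.to_dict(),
            "truss_laws": {k: v.to_dict() for k, v in self.truss_laws.items()},
            "contact_pairs": [c.to_dict() for c in self.contact_pairs],
            "load_case": self.load_case.to_dict(),
            "pose": self.pose.to_dict() if self.pose else None,
            "shell_props": dict(self.shell_props),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KneeModel":
        return cls(
            mesh=Mesh.from_dict(d["mesh"]),
            truss_laws={k: TrussLaw.from_dict(v) for k, v in d["truss_laws"].items()},
            contact_pairs=[ContactPair.from_dict(c) for c in d["contact_pairs"]],
            load_case=LoadCase.from_dict(d["load_case"]),
            pose=PosePrescription.from_dict(d["pose"]) if d.get("pose") else None,
            shell_props=dict(d["shell_props"]),
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load_json(cls, path: str | Path) -> "KneeModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_external_forces(model: KneeModel) -> np.ndarray:
    """Nodal external force array (n, 3) from the load case.

    The vertical GRF is distributed over the distal tibia surface with
    area-weighted (tributary-area) nodal forces; flexor muscle tractions act
    as nodal forces along their anatomical lines at the labelled attachment
    nodes. Horizontal GRF components are included only when the load case
    explicitly enables them.
    """
    mesh = model.mesh
    lc = model.load_case
    f = np.zeros((mesh.n_nodes, 3))

    facets = mesh.facet_sets.get("tibia_distal_facets")
    if facets is None or len(facets) == 0:
        raise ValueError("missing facet set 'tibia_distal_facets' for GRF application")
    areas = mesh.tri_areas(facets)
    grf = np.array([0.0, 0.0, lc.grf_upward])
    if lc.apply_horizontal_grf:
        grf[0] += lc.grf_inward
        grf[1] += lc.grf_forward
    total_area = areas.sum()
    for tri, a in zip(facets, areas):
        for n in tri:
            f[n] += grf * (a / total_area) / 3.0

    for muscle, force in (
        ("biceps_femoris", lc.biceps_femoris),
        ("semimembranosus", lc.semimembranosus),
        ("semitendinosus_gracilis", lc.semitendinosus_gracilis),
    ):
        src = mesh.node_sets.get(f"attach_{muscle}")
        dst = mesh.node_sets.get(f"attach_{muscle}_target")
        if src is None or dst is None:
            continue
        src, dst = int(np.asarray(src).ravel()[0]), int(np.asarray(dst).ravel()[0])
        axis = mesh.points[dst] - mesh.points[src]
        axis = axis / np.linalg.norm(axis)
        f[src] += force * axis
    return f
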