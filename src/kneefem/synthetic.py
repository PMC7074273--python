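"""Synthetic inputs for the whole pipeline: CT phantoms, knee meshes, gait data.

The CT phantom emulates a knee-like acquisition with a QCT calibration
phantom in the field of view: two bone bodies with a dense cortical shell and
a trabecular interior density gradient, plus rods of known equivalent density
for HU→density calibration. HU values are synthesised by inverting the linear
calibration ρ = a·HU + b, so the zero-noise round trip is exact by
construction.

The knee mesh is parametric and deliberately simplified — condyle-crowned
femur and tibia blocks with an interposed tibial-cartilage layer and two
meniscus-like spacer blocks, a shell-covered patellar patch on the femur
anterior surface, and labelled truss attachments — not an anatomical
reconstruction. Soft-tissue background is fixed at 40 HU and air at −1000 HU.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from kneefem.mesh import Mesh, box_mesh, grid_lines, boundary_faces, merge_meshes
from kneefem.volume import CTVolume
from kneefem.model import (
    KneeModel,
    ContactPair,
    LoadCase,
    patellar_tendon_law,
    cruciate_collateral_law,
    compose_joint_rotation,
)
from kneefem.gait import GaitRecording, EMG_CHANNELS, MARKER_NAMES

SOFT_TISSUE_HU = 40.0
AIR_HU = -1000.0


# ================================================================= phantom

@dataclass
class BoneBody:
    """Axis-aligned box bone body with cortical shell and trabecular gradient."""

    name: str
    lo: tuple = (-18.0, -12.0, -30.0)
    hi: tuple = (18.0, 12.0, 0.0)
    cortical_thickness: float = 3.0  # mm
    cortical_density: float = 1.8  # g/cm³
    trabecular_density: tuple = (0.25, 0.55)  # g/cm³, bottom → top along z

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "lo": list(self.lo),
            "hi": list(self.hi),
            "cortical_thickness": self.cortical_thickness,
            "cortical_density": self.cortical_density,
            "trabecular_density": list(self.trabecular_density),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoneBody":
        return cls(
            name=d["name"],
            lo=tuple(d["lo"]),
            hi=tuple(d["hi"]),
            cortical_thickness=d["cortical_thickness"],
            cortical_density=d["cortical_density"],
            trabecular_density=tuple(d["trabecular_density"]),
        )


def default_bone_geometry() -> list:
    """Two bone bodies matching the default knee mesh footprint."""
    return [
        BoneBody("femur", lo=(-18.0, -12.0, 4.0), hi=(18.0, 12.0, 34.6)),
        BoneBody("tibia", lo=(-18.0, -12.0, -30.0), hi=(18.0, 12.0, 2.0)),
    ]


@dataclass
class PhantomSpec:
    """Parameters of the synthetic CT acquisition."""

    volume_shape: tuple = (36, 36, 52)
    spacing: tuple = (1.5, 1.5, 1.5)
    origin: tuple = (-26.0, -26.0, -36.0)
    rod_densities: tuple = (0.2, 0.6, 1.0, 1.4)  # g/cm³
    rod_radius: float = 3.0  # mm
    rod_y: float = -20.0  # rod row offset, mm
    rod_z: tuple = (-25.0, -5.0)
    true_calibration: tuple = (0.001, 0.0)  # (a, b): HU = (ρ − b)/a
    bone_geometry: list = field(default_factory=default_bone_geometry)
    noise_sd: float = 0.0  # HU
    air_border: int = 1  # voxels of air at the volume boundary
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if any(r < 0 for r in self.rod_densities):
            raise ValueError("rod densities must be non-negative")
        if self.true_calibration[0] <= 0:
            raise ValueError("calibration slope must be positive")

    def rod_centers(self) -> np.ndarray:
        """Deterministic rod centre (x, y) positions, evenly spaced in x."""
        n = len(self.rod_densities)
        ext_x = self.origin[0] + self.spacing[0] * (self.volume_shape[0] - 1)
        pad = self.rod_radius + self.spacing[0] * (self.air_border + 1)
        xs = np.linspace(self.origin[0] + pad, ext_x - pad, n)
        return np.column_stack([xs, np.full(n, self.rod_y)])


def make_ct_phantom(spec: PhantomSpec) -> tuple[CTVolume, np.ndarray]:
    """Synthesise the phantom volume and its ground-truth density map.

    Returns (volume, density) where ``density[i,j,k]`` is the density each
    voxel's noise-free HU encodes under the spec's true calibration (clamped
    below at zero, matching the mapping convention).
    """
    a, b = spec.true_calibration
    shape = tuple(int(s) for s in spec.volume_shape)
    spacing = np.array(spec.spacing, float)
    origin = np.array(spec.origin, float)
    hi_corner = origin + spacing * (np.array(shape) - 1)

    grids = [origin[k] + spacing[k] * np.arange(shape[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*grids, indexing="ij")
    hu = np.full(shape, SOFT_TISSUE_HU)

    for body in spec.bone_geometry:
        lo, hi = np.array(body.lo), np.array(body.hi)
        if np.any(lo < origin - spacing / 2) or np.any(hi > hi_corner + spacing / 2):
            raise ValueError(f"bone body {body.name!r} exceeds the volume bounds")
        inside = (
            (X >= lo[0]) & (X <= hi[0]) & (Y >= lo[1]) & (Y <= hi[1]) & (Z >= lo[2]) & (Z <= hi[2])
        )
        depth = np.minimum.reduce(
            [X - lo[0], hi[0] - X, Y - lo[1], hi[1] - Y, Z - lo[2], hi[2] - Z]
        )
        frac = np.clip((Z - lo[2]) / max(hi[2] - lo[2], 1e-9), 0, 1)
        rho_trab = body.trabecular_density[0] + frac * (
            body.trabecular_density[1] - body.trabecular_density[0]
        )
        rho_body = np.where(depth <= body.cortical_thickness, body.cortical_density, rho_trab)
        hu = np.where(inside, (rho_body - b) / a, hu)

    centers = spec.rod_centers()
    for (cx, cy), rho in zip(centers, spec.rod_densities):
        if (
            cx - spec.rod_radius < origin[0]
            or cx + spec.rod_radius > hi_corner[0]
            or cy - spec.rod_radius < origin[1]
            or cy + spec.rod_radius > hi_corner[1]
            or spec.rod_z[0] < origin[2]
            or spec.rod_z[1] > hi_corner[2]
        ):
            raise ValueError(f"calibration rod at x={cx:.1f} exceeds the volume bounds")
        inside = ((X - cx) ** 2 + (Y - cy) ** 2 <= spec.rod_radius**2) & (
            (Z >= spec.rod_z[0]) & (Z <= spec.rod_z[1])
        )
        hu = np.where(inside, (rho - b) / a, hu)

    if spec.air_border > 0:
        k = spec.air_border
        mask = np.zeros(shape, dtype=bool)
        mask[:k] = mask[-k:] = True
        mask[:, :k] = mask[:, -k:] = True
        mask[:, :, :k] = mask[:, :, -k:] = True
        hu = np.where(mask, AIR_HU, hu)

    density = np.maximum(a * hu + b, 0.0)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sd, size=shape)

    return CTVolume(hu, spacing, origin), density


def rod_masks(spec: PhantomSpec, volume: CTVolume) -> list[np.ndarray]:
    """Boolean voxel mask per calibration rod (eroded by one voxel radius to
    avoid partial-volume edges)."""
    shape = volume.shape
    grids = [volume.origin[k] + volume.spacing[k] * np.arange(shape[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*grids, indexing="ij")
    masks = []
    r_in = max(spec.rod_radius - max(volume.spacing[:2]), 0.5)
    for cx, cy in spec.rod_centers():
        masks.append(
            ((X - cx) ** 2 + (Y - cy) ** 2 <= r_in**2)
            & (Z >= spec.rod_z[0] + volume.spacing[2])
            & (Z <= spec.rod_z[1] - volume.spacing[2])
        )
    return masks


def rod_samples(spec: PhantomSpec, volume: CTVolume) -> list[tuple[float, float]]:
    """(mean HU, known density) calibration samples from the rod regions."""
    return [
        (float(volume.data[m].mean()), float(rho))
        for m, rho in zip(rod_masks(spec, volume), spec.rod_densities)
    ]


# ================================================================= knee mesh

KNEE_X = (-18.0, 18.0)
KNEE_Y = (-12.0, 12.0)
TIBIA_Z = (-30.0, 0.0)
CARTILAGE_TOP = 2.0
MENISCUS_TOP = 4.0
MENISCUS_WIDTH = 10.0
FEMUR_Z = (4.6, 34.6)
CONDYLE_OFFSET = 9.0  # condyle centres at x = ±9
CONDYLE_RADIUS = 80.0  # paraboloid crown radius, mm


def _condyle_crown(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Height of the femur inferior surface above its lowest points: a pair of
    shallow paraboloid condyles (medial and lateral)."""
    r2m = (x - CONDYLE_OFFSET) ** 2 + y**2
    r2l = (x + CONDYLE_OFFSET) ** 2 + y**2
    return np.minimum(r2m, r2l) / (2.0 * CONDYLE_RADIUS)


def make_knee_mesh(resolution: float = 3.0) -> KneeModel:
    """Parametric simplified knee: femur and tibia blocks, tibial cartilage
    layer, medial/lateral meniscus spacers, patellar shell patch, and six
    ligament/tendon trusses, with the node/facet sets the solver needs.

    ``resolution`` is the target element edge length in mm, accepted over
    [0.5, 5].
    """
    if not (0.5 <= resolution <= 5.0):
        raise ValueError("resolution must lie in [0.5, 5] mm")
    res = float(resolution)
    xs = grid_lines(*KNEE_X, res)
    ys = grid_lines(*KNEE_Y, res)

    # tibia + conforming cartilage layer
    zs_tib = np.append(grid_lines(*TIBIA_Z, res), CARTILAGE_TOP)
    p_tib, t_tib = box_mesh(xs, ys, zs_tib)

    # menisci
    zs_men = grid_lines(CARTILAGE_TOP, MENISCUS_TOP, min(res, MENISCUS_TOP - CARTILAGE_TOP))
    xs_med = grid_lines(KNEE_X[1] - MENISCUS_WIDTH, KNEE_X[1], res)
    xs_lat = grid_lines(KNEE_X[0], KNEE_X[0] + MENISCUS_WIDTH, res)
    p_men_m, t_men_m = box_mesh(xs_med, ys, zs_men)
    p_men_l, t_men_l = box_mesh(xs_lat, ys, zs_men)

    # femur with condyle-crowned inferior surface
    zs_fem = grid_lines(0.0, FEMUR_Z[1] - FEMUR_Z[0], res)
    p_fem, t_fem = box_mesh(xs, ys, zs_fem)
    h = FEMUR_Z[1] - FEMUR_Z[0]
    crown = _condyle_crown(p_fem[:, 0], p_fem[:, 1])
    p_fem = p_fem.copy()
    p_fem[:, 2] = FEMUR_Z[0] + p_fem[:, 2] + crown * (1.0 - p_fem[:, 2] / h)

    points, tets, tet_part, offs = merge_meshes(
        [
            (p_tib, t_tib, "tibia"),
            (p_men_m, t_men_m, "meniscus"),
            (p_men_l, t_men_l, "meniscus"),
            (p_fem, t_fem, "femur"),
        ]
    )
    # relabel the cartilage layer of the tibia block
    cent = points[tets].mean(axis=1)
    cart = (tet_part == "tibia") & (cent[:, 2] > TIBIA_Z[1])
    tet_part[cart] = "cartilage"

    mesh = Mesh(points=points, tets=tets, tet_part=tet_part)
    mesh.validate()
    tol = 1e-6

    def _surface(part_mask, predicate, name):
        faces = boundary_faces(tets[part_mask])
        p0, p1, p2 = points[faces[:, 0]], points[faces[:, 1]], points[faces[:, 2]]
        normal = np.cross(p1 - p0, p2 - p0)
        normal /= np.linalg.norm(normal, axis=1, keepdims=True)
        centroid = (p0 + p1 + p2) / 3.0
        sel = predicate(centroid, normal)
        mesh.facet_sets[f"{name}_facets"] = faces[sel]
        mesh.node_sets[f"{name}_nodes"] = np.unique(faces[sel].ravel())

    is_tibia_block = (tet_part == "tibia") | (tet_part == "cartilage")
    is_men = tet_part == "meniscus"
    is_fem = tet_part == "femur"

    _surface(is_tibia_block, lambda c, n: (n[:, 2] < -0.7) & (c[:, 2] < TIBIA_Z[0] + tol), "tibia_distal")
    _surface(is_tibia_block, lambda c, n: (n[:, 2] > 0.7) & (c[:, 2] > CARTILAGE_TOP - tol), "cartilage_superior")
    _surface(is_men, lambda c, n: (n[:, 2] > 0.7) & (c[:, 2] > MENISCUS_TOP - tol), "meniscus_superior")
    _surface(is_men, lambda c, n: (n[:, 2] < -0.7) & (c[:, 2] < CARTILAGE_TOP + tol), "meniscus_inferior")
    _surface(is_fem, lambda c, n: n[:, 2] < -0.7, "femur_inferior")
    _surface(is_fem, lambda c, n: n[:, 2] > 0.7, "femur_proximal")

    # meniscus inner-rim band (innermost node columns at the inferior surface),
    # tied to the tibial cartilage
    dx_med = xs_med[1] - xs_med[0]
    inf_nodes = mesh.node_sets["meniscus_inferior_nodes"]
    px = points[inf_nodes, 0]
    rim = inf_nodes[
        ((px >= KNEE_X[1] - MENISCUS_WIDTH - tol) & (px <= KNEE_X[1] - MENISCUS_WIDTH + dx_med + tol))
        | ((px <= KNEE_X[0] + MENISCUS_WIDTH + tol) & (px >= KNEE_X[0] + MENISCUS_WIDTH - dx_med - tol))
    ]
    mesh.node_sets["meniscus_rim_nodes"] = rim
    mesh.node_sets["meniscus_inferior_nodes"] = np.setdiff1d(inf_nodes, rim)

    # patellar shell patch on the femur anterior surface
    fem_faces = boundary_faces(tets[is_fem])
    p0, p1, p2 = points[fem_faces[:, 0]], points[fem_faces[:, 1]], points[fem_faces[:, 2]]
    normal = np.cross(p1 - p0, p2 - p0)
    normal /= np.linalg.norm(normal, axis=1, keepdims=True)
    centroid = (p0 + p1 + p2) / 3.0
    patch_sel = (
        (normal[:, 1] > 0.7)
        & (np.abs(centroid[:, 0]) < CONDYLE_OFFSET)
        & (centroid[:, 2] > 12.0)
        & (centroid[:, 2] < 28.0)
    )
    patch = fem_faces[patch_sel]
    if len(patch) == 0:
        raise RuntimeError("patellar patch selection is empty")
    mesh.tris = patch
    mesh.tri_part = np.full(len(patch), "patella", dtype=object)
    patch_nodes = np.unique(patch.ravel())
    mesh.node_sets["patella_patch_nodes"] = patch_nodes

    def nearest(target, candidates=None):
        cand = np.arange(len(mesh.points)) if candidates is None else np.asarray(candidates)
        d = np.linalg.norm(mesh.points[cand] - np.asarray(target, float), axis=1)
        return int(cand[int(np.argmin(d))])

    tibia_nodes = mesh.part_nodes("tibia")
    femur_nodes = mesh.part_nodes("femur")

    # quadriceps actuation anchor above the patch
    top_patch = nearest((0.0, KNEE_Y[1], 26.0), patch_nodes)
    anchor_xyz = mesh.points[top_patch] + np.array([0.0, 3.0, 12.0])
    mesh.points = np.vstack([mesh.points, anchor_xyz])
    anchor = len(mesh.points) - 1
    mesh.node_sets["quad_anchor_nodes"] = np.array([anchor])

    low_patch = nearest((0.0, KNEE_Y[1], 14.0), patch_nodes)
    tib_tuber = nearest((0.0, KNEE_Y[1], TIBIA_Z[1]), tibia_nodes)

    trusses = [
        (top_patch, anchor, "quadriceps"),
        (low_patch, tib_tuber, "patellar_ligament"),
        (nearest((KNEE_X[1], 0.0, 6.0), femur_nodes), nearest((KNEE_X[1], 0.0, 0.0), tibia_nodes), "mcl"),
        (nearest((KNEE_X[0], 0.0, 6.0), femur_nodes), nearest((KNEE_X[0], 0.0, 0.0), tibia_nodes), "lcl"),
        (nearest((2.0, -4.0, 5.5), femur_nodes), nearest((-2.0, 4.0, 0.0), tibia_nodes), "acl"),
        (nearest((-2.0, 4.0, 5.5), femur_nodes), nearest((2.0, -4.0, 0.0), tibia_nodes), "pcl"),
    ]
    mesh.trusses = np.array([(a, b) for a, b, _ in trusses], dtype=int)
    mesh.truss_names = [n for _, _, n in trusses]

    # flexor muscle attachment lines (forces applied along these axes)
    for name, tib_xy, fem_xy in (
        ("biceps_femoris", (-14.0, KNEE_Y[0]), (-10.0, KNEE_Y[0])),
        ("semimembranosus", (12.0, KNEE_Y[0]), (8.0, KNEE_Y[0])),
        ("semitendinosus_gracilis", (6.0, KNEE_Y[0]), (4.0, KNEE_Y[0])),
    ):
        mesh.node_sets[f"attach_{name}"] = np.array(
            [nearest((tib_xy[0], tib_xy[1], TIBIA_Z[1]), tibia_nodes)]
        )
        mesh.node_sets[f"attach_{name}_target"] = np.array(
            [nearest((fem_xy[0], fem_xy[1], 20.0), femur_nodes)]
        )

    laws = {
        "quadriceps": patellar_tendon_law(),
        "patellar_ligament": patellar_tendon_law(),
        "mcl": cruciate_collateral_law(),
        "lcl": cruciate_collateral_law(),
        "acl": cruciate_collateral_law(),
        "pcl": cruciate_collateral_law(),
    }
    pairs = [
        ContactPair("cartilage_superior_nodes", "femur_inferior_facets"),
        ContactPair("meniscus_superior_nodes", "femur_inferior_facets"),
        ContactPair("meniscus_inferior_nodes", "cartilage_superior_facets"),
        ContactPair("meniscus_rim_nodes", "cartilage_superior_facets", tied=True),
    ]
    return KneeModel(mesh=mesh, truss_laws=laws, contact_pairs=pairs, load_case=LoadCase())


# ================================================================= gait

@dataclass
class GaitFixtureSpec:
    """Parameters of the synthetic gait trial."""

    stance_duration: float = 0.6  # s
    grf_peak: float = 808.95  # N, vertical
    marker_noise_sd: float = 0.0  # mm
    emg_burst_centers: dict = field(
        default_factory=lambda: {"RF": 0.10, "VM": 0.12, "VL": 0.12, "BF": 0.90, "ST": 0.92}
    )
    emg_burst_width: float = 0.06  # fraction of cycle (gaussian sd)
    knee_angles: tuple = (12.21, 14.62, -3.28)  # inversion, bending, inward (deg)
    tibia_angles: tuple = (11.5, 13.3, 7.7)  # inversion, bending, inward (deg)
    marker_rate: float = 200.0  # Hz
    grf_rate: float = 1200.0  # Hz
    emg_rate: float = 2000.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.marker_rate, self.grf_rate, self.emg_rate) <= 0:
            raise ValueError("sampling rates must be positive")
        if self.stance_duration <= 0:
            raise ValueError("stance duration must be positive")
        for ch, c in self.emg_burst_centers.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"EMG burst centre for {ch} must lie in [0, 1]")

    @property
    def cycle_duration(self) -> float:
        """Stance occupies 60% of the gait cycle."""
        return self.stance_duration / 0.6

    @property
    def stance_start(self) -> float:
        return 0.2 * self.cycle_duration


# marker template positions in segment-local coordinates (mm); the femur frame
# has its origin at the knee marker, the tibia frame at the ankle marker, Z up.
_FEMUR_LOCAL = {
    "RKNE": (0.0, 0.0, 0.0),
    "RTHI": (60.0, 0.0, 180.0),
    "RASI": (40.0, 90.0, 420.0),
    "RPSI": (-40.0, -90.0, 380.0),
    "LASI": (-300.0, 90.0, 420.0),
    "LPSI": (-340.0, -90.0, 380.0),
}
_TIBIA_LOCAL = {
    "RANK": (0.0, 0.0, 0.0),
    "RTIB": (55.0, 0.0, 150.0),
    "RHEE": (0.0, -60.0, -40.0),
    "RTOE": (0.0, 120.0, -50.0),
}
_SHANK_LENGTH = 380.0  # knee-to-ankle distance, mm


def make_gait_fixture(spec: GaitFixtureSpec) -> GaitRecording:
    """Generate a marker/GRF/EMG recording posed at the LR-phase angles.

    The leg holds the prescribed tibia–floor and knee angles throughout the
    trial while the whole marker set translates forward with a small vertical
    bob (a rigid motion, so joint angles are unaffected); the vertical GRF is
    an M-shaped curve that is zero outside stance and peaks at ``grf_peak``;
    EMG channels carry amplitude-modulated bursts at the prescribed cycle
    fractions. Output is bit-identical for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    T = spec.cycle_duration
    t0 = spec.stance_start
    t1 = t0 + spec.stance_duration

    inv_t, bend_t, inw_t = spec.tibia_angles
    R_tib = compose_joint_rotation(bend_t, inv_t, inw_t).as_matrix()
    inv_k, bend_k, inw_k = spec.knee_angles
    R_rel = compose_joint_rotation(bend_k, inv_k, inw_k).as_matrix()
    R_fem = R_tib @ R_rel.T

    t_m = np.arange(0.0, T, 1.0 / spec.marker_rate)
    knee0 = np.array([0.0, 0.0, 500.0])
    # global rigid translation: forward progression plus vertical bob
    drift = np.column_stack(
        [
            np.zeros_like(t_m),
            1200.0 * t_m / T,
            10.0 * np.sin(2 * np.pi * t_m / T),
        ]
    )
    cols = {"time": t_m}
    ankle0 = knee0 - R_tib @ np.array([0.0, 0.0, _SHANK_LENGTH])
    for name in MARKER_NAMES:
        if name in _FEMUR_LOCAL:
            base = knee0 + R_fem @ np.array(_FEMUR_LOCAL[name])
        else:
            base = ankle0 + R_tib @ np.array(_TIBIA_LOCAL[name])
        pos = base[None, :] + drift
        if spec.marker_noise_sd > 0:
            pos = pos + rng.normal(0.0, spec.marker_noise_sd, size=pos.shape)
        cols[f"{name}_x"], cols[f"{name}_y"], cols[f"{name}_z"] = pos.T
    markers = pd.DataFrame(cols)

    t_g = np.arange(0.0, T, 1.0 / spec.grf_rate)
    s = (t_g - t0) / spec.stance_duration
    sc = np.clip(s, 0.0, 1.0)
    # double-hump vertical GRF with a steep (heel-strike-like) onset
    shape = np.where(
        (s >= 0) & (s <= 1), np.sqrt(np.sin(np.pi * sc)) * (1.0 + 0.3 * np.cos(2 * np.pi * sc)), 0.0
    )
    shape = np.clip(shape, 0.0, None)
    fz = spec.grf_peak * shape / shape.max()
    fx = (26.08 / 808.95) * fz
    fy = -0.25 * spec.grf_peak * np.where((s >= 0) & (s <= 1), np.sin(2 * np.pi * sc), 0.0) * shape / shape.max()
    grf = pd.DataFrame({"time": t_g, "fx": fx, "fy": fy, "fz": fz})

    t_e = np.arange(0.0, T, 1.0 / spec.emg_rate)
    emg_cols = {"time": t_e}
    sos = butter(2, [20.0, 450.0], btype="band", fs=spec.emg_rate, output="sos")
    activations = {}
    for ch in EMG_CHANNELS:
        c = spec.emg_burst_centers.get(ch, 0.5) * T
        env = np.exp(-0.5 * ((t_e - c) / (spec.emg_burst_width * T)) ** 2)
        carrier = np.sin(2 * np.pi * 80.0 * t_e + rng.uniform(0, 2 * np.pi))
        noise = sosfiltfilt(sos, rng.normal(0.0, 1.0, len(t_e)))
        noise = noise / np.abs(noise).max()
        emg_cols[ch] = env * (0.9 * carrier + 0.1 * noise) + 0.005 * noise
        activations[ch] = {"center": spec.emg_burst_centers.get(ch, 0.5), "width": spec.emg_burst_width}

    emg = pd.DataFrame(emg_cols)
    meta = {
        "stance_start": t0,
        "stance_end": t1,
        "cycle_duration": T,
        "grf_peak": spec.grf_peak,
        "knee_angles": list(spec.knee_angles),
        "tibia_angles": list(spec.tibia_angles),
        "activations": activations,
        "seed": spec.seed,
    }
    return GaitRecording(markers=markers, grf=grf, emg=emg, meta=meta)
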