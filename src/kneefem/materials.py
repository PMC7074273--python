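"""HU→density calibration and density→Young's-modulus mapping for bone.

Bone density ρ (g/cm³) is a linear function of the CT value: ρ = a·HU + b,
with (a, b) fitted to calibration-phantom rods of known density scanned with
the subject, or taken from a published default calibration for a 125 kV tube
voltage when no phantom is available. Young's modulus then follows Keyak's
piecewise density–modulus law; Poisson's ratio is the constant 0.4
conventionally used for bone. Non-bone tissues carry constant moduli
(cartilage 20 MPa — 100 MPa for fibular cartilage — meniscus 20 MPa,
ligament 0.1 MPa), all with ν = 0.4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from kneefem.mesh import Mesh
from kneefem.volume import CTVolume

#: Stability floor for Young's modulus, MPa.
E_FLOOR = 0.001

#: Poisson's ratio used for bone and all soft-tissue parts.
POISSON = 0.4

#: Default published calibration, valid for a 125 kV tube voltage:
#: ρ = 0 for HU ≤ −1, else ρ = (HU + 1.4246) × 0.001 × 1.0580.
DEFAULT_125KV = "default125kV"

#: Constant tissue moduli (MPa), ν = 0.4 for every entry.
TISSUE_CONSTANTS = {
    "cartilage": 20.0,
    "cartilage_fibula": 100.0,
    "meniscus": 20.0,
    "ligament": 0.1,
}


@dataclass
class DensityCalibration:
    """Linear HU→density map ρ = a·HU + b (ρ in g/cm³).

    ``source`` is either ``"phantom"`` (fitted) or ``"default125kV"``; the
    default applies the published 125 kV piecewise form instead of the plain
    line.
    """

    a: float
    b: float
    source: str = "phantom"
    residual_sd: float = 0.0
    stderr_a: float = float("nan")
    stderr_b: float = float("nan")

    def __post_init__(self) -> None:
        if self.source not in ("phantom", DEFAULT_125KV):
            raise ValueError(f"unknown calibration source {self.source!r}")
        if self.a <= 0:
            raise ValueError("calibration slope must be positive")

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "source": self.source,
            "residual_sd": self.residual_sd,
            "stderr_a": self.stderr_a,
            "stderr_b": self.stderr_b,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DensityCalibration":
        return cls(**d)


def default_calibration() -> DensityCalibration:
    """The published 125 kV fallback calibration."""
    return DensityCalibration(a=0.001 * 1.0580, b=1.4246 * 0.001 * 1.0580, source=DEFAULT_125KV)


def calibrate_hu_density(samples) -> DensityCalibration:
    """Least-squares fit of ρ = a·HU + b to (mean HU, known density) pairs.

    Parameters
    ----------
    samples : sequence of (hu, density)
        At least two pairs with distinct HU values.
    """
    samples = np.asarray(samples, dtype=float).reshape(-1, 2)
    hu, rho = samples[:, 0], samples[:, 1]
    if len(np.unique(hu)) < 2:
        raise ValueError("need at least 2 samples with distinct HU values to calibrate")
    A = np.column_stack([hu, np.ones_like(hu)])
    coef, *_ = np.linalg.lstsq(A, rho, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    resid = rho - (a * hu + b)
    dof = max(len(hu) - 2, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    return DensityCalibration(
        a=a,
        b=b,
        source="phantom",
        residual_sd=float(np.sqrt(s2)),
        stderr_a=float(np.sqrt(cov[0, 0])),
        stderr_b=float(np.sqrt(cov[1, 1])),
    )


def hu_to_density(hu, cal: DensityCalibration) -> np.ndarray | float:
    """Convert HU to density (g/cm³), clamped below at 0.

    With the 125 kV default: ρ = 0 for HU ≤ −1, else
    (HU + 1.4246) × 0.001 × 1.0580. With a phantom calibration: a·HU + b,
    clamped at 0.
    """
    hu_arr = np.asarray(hu, dtype=float)
    if cal.source == DEFAULT_125KV:
        rho = np.where(hu_arr <= -1.0, 0.0, (hu_arr + 1.4246) * 0.001 * 1.0580)
    else:
        rho = np.maximum(cal.a * hu_arr + cal.b, 0.0)
    return float(rho) if np.isscalar(hu) else rho


def density_to_youngs(rho) -> np.ndarray | float:
    """Keyak's piecewise density→modulus law, E in MPa.

    E = 0.001 at ρ = 0; 33900·ρ^2.20 for 0 < ρ ≤ 0.27; 5307·ρ + 469 for
    0.27 < ρ < 0.6; 10200·ρ^2.01 for ρ ≥ 0.6. The law is continuous at both
    breakpoints to better than 1 MPa and monotone non-decreasing.
    """
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr < 0):
        raise ValueError("density must be non-negative")
    with np.errstate(divide="ignore"):
        E = np.where(
            rho_arr == 0,
            E_FLOOR,
            np.where(
                rho_arr <= 0.27,
                33900.0 * rho_arr**2.20,
                np.where(rho_arr < 0.6, 5307.0 * rho_arr + 469.0, 10200.0 * rho_arr**2.01),
            ),
        )
    E = np.maximum(E, E_FLOOR)
    return float(E) if np.isscalar(rho) else E


def keyak_yield_stress(rho) -> np.ndarray | float:
    """Keyak's density→yield-stress relation, MPa (stored, unused by the linear solve).

    S = 137·ρ^1.88 for ρ < 0.317 (trabecular), 114·ρ^1.72 otherwise.
    """
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr < 0):
        raise ValueError("density must be non-negative")
    S = np.where(rho_arr < 0.317, 137.0 * rho_arr**1.88, 114.0 * rho_arr**1.72)
    return float(S) if np.isscalar(rho) else S


@dataclass
class MaterialField:
    """Per-tet material record: density (g/cm³), E (MPa), ν, part label."""

    rho: np.ndarray
    E: np.ndarray
    nu: np.ndarray
    part: np.ndarray
    yield_stress: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        self.nu = np.asarray(self.nu, dtype=float)
        if np.any(self.rho < 0) or np.any(self.E < E_FLOOR - 1e-12):
            raise ValueError("invalid material field (negative density or E below floor)")


BONE_PARTS = ("femur", "tibia", "fibula", "patella")


def assign_element_materials(
    mesh: Mesh,
    volume: CTVolume | None,
    cal: DensityCalibration | None,
    tissue_constants: dict | None = None,
    sampling: str = "vertices+centroid",
    with_yield: bool = False,
) -> MaterialField:
    """Assign heterogeneous bone materials from CT and constants to soft parts.

    Bone tets (parts in ``BONE_PARTS``) sample the volume's HU field — by
    default at the four vertices plus the centroid, optionally averaging all
    voxel centres inside the element's bounding sphere — convert the mean HU to
    density, and density to E via Keyak's law. Other parts take the constant
    moduli from ``tissue_constants`` (the built-in tissue constants by default).
    """
    tissue = dict(TISSUE_CONSTANTS)
    if tissue_constants:
        tissue.update(tissue_constants)
    m = len(mesh.tets)
    rho = np.zeros(m)
    E = np.zeros(m)
    nu = np.full(m, POISSON)

    is_bone = np.isin(mesh.tet_part.astype(str), BONE_PARTS)
    if np.any(is_bone):
        if volume is None or cal is None:
            raise ValueError("bone parts present: a CT volume and calibration are required")
        bone_ids = np.where(is_bone)[0]
        verts = mesh.points[mesh.tets[bone_ids]]  # (k, 4, 3)
        if sampling == "vertices+centroid":
            pts = np.concatenate([verts, verts.mean(axis=1, keepdims=True)], axis=1)  # (k,5,3)
            flat = pts.reshape(-1, 3)
            inside = volume.contains(flat).reshape(len(bone_ids), -1)
            if not np.all(inside.any(axis=1)):
                bad = bone_ids[~inside.any(axis=1)][0]
                raise ValueError(f"bone element {bad} lies entirely outside the CT volume")
            hu_flat = np.full(len(flat), np.nan)
            ok = volume.contains(flat)
            hu_flat[ok] = volume.sample_hu(flat[ok])
            hu_mean = np.nanmean(hu_flat.reshape(len(bone_ids), -1), axis=1)
        elif sampling == "voxels":
            hu_mean = np.empty(len(bone_ids))
            for n, eid in enumerate(bone_ids):
                hu_mean[n] = _voxel_average_hu(mesh, eid, volume)
        else:
            raise ValueError(f"unknown sampling mode {sampling!r}")
        rho[bone_ids] = hu_to_density(hu_mean, cal)
        E[bone_ids] = density_to_youngs(rho[bone_ids])

    for part in np.unique(mesh.tet_part[~is_bone].astype(str)) if np.any(~is_bone) else []:
        if part not in tissue:
            raise ValueError(f"no tissue constant defined for part {part!r}")
        sel = mesh.tet_part.astype(str) == part
        E[sel] = tissue[part]
        rho[sel] = 0.0

    E = np.maximum(E, E_FLOOR)
    field_yield = keyak_yield_stress(rho) if with_yield else None
    return MaterialField(rho=rho, E=E, nu=nu, part=mesh.tet_part.copy(), yield_stress=field_yield)


def _voxel_average_hu(mesh: Mesh, eid: int, volume: CTVolume) -> float:
    """Average HU over voxel centres falling inside tet ``eid``."""
    verts = mesh.points[mesh.tets[eid]]
    lo = verts.min(axis=0)
    hi = verts.max(axis=0)
    i0 = np.floor((lo - volume.origin) / volume.spacing).astype(int)
    i1 = np.ceil((hi - volume.origin) / volume.spacing).astype(int) + 1
    i0 = np.maximum(i0, 0)
    i1 = np.minimum(i1, volume.shape)
    if np.any(i0 >= i1):
        raise ValueError(f"bone element {eid} lies entirely outside the CT volume")
    grids = [np.arange(i0[k], i1[k]) * volume.spacing[k] + volume.origin[k] for k in range(3)]
    gx, gy, gz = np.meshgrid(*grids, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    # barycentric inside test
    T = np.column_stack([verts[1] - verts[0], verts[2] - verts[0], verts[3] - verts[0]])
    lam = np.linalg.solve(T, (pts - verts[0]).T).T
    inside = (lam >= -1e-12).all(axis=1) & (lam.sum(axis=1) <= 1 + 1e-12)
    if not inside.any():
        # small element between voxel centres: fall back to centroid sample
        return float(volume.sample_hu(verts.mean(axis=0)[None])[0])
    ii = np.floor((pts[inside] - volume.origin) / volume.spacing + 0.5).astype(int)
    return float(volume.data[ii[:, 0], ii[:, 1], ii[:, 2]].mean())
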