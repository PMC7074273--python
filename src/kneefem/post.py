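"""Equivalent stresses and joint-contact summaries.

Equivalent stress uses the von Mises criterion √(3·J₂) for cartilage and the
Drucker–Prager form √(3·J₂) + α·I₁ for bone. The pressure-sensitivity α is a
free parameter defaulting to 0, at which the two criteria coincide on every
stress state.

Contact summaries aggregate the per-slave-node penalty tractions of a
converged solve: total contact area (tributary areas of nodes carrying a
nonzero normal traction), area-weighted average and maximum contact pressure,
and the resultant joint reaction force. A medial/lateral partition plane
splits the contact force between the two compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from kneefem.solver import SolveResult, ContactState

#: Faces count toward the contact area when |normal traction| exceeds this (MPa).
CONTACT_TRACTION_EPS = 1e-9


def _check_symmetric(sigma: np.ndarray) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape[-2:] != (3, 3):
        raise ValueError("stress must be a 3×3 tensor (or an array of them)")
    if not np.allclose(sigma, np.swapaxes(sigma, -1, -2), rtol=1e-8, atol=1e-8):
        raise ValueError("stress tensor must be symmetric")
    return sigma


def von_mises(sigma: np.ndarray) -> np.ndarray | float:
    """von Mises equivalent stress √(3·J₂) of the deviator, MPa."""
    s = _check_symmetric(sigma)
    scalar = s.ndim == 2
    s = s.reshape(-1, 3, 3)
    tr = np.trace(s, axis1=1, axis2=2)
    dev = s - tr[:, None, None] / 3.0 * np.eye(3)
    j2 = 0.5 * np.einsum("nij,nij->n", dev, dev)
    vm = np.sqrt(3.0 * j2)
    return float(vm[0]) if scalar else vm


def drucker_prager_eq(sigma: np.ndarray, alpha: float = 0.0) -> np.ndarray | float:
    """Drucker–Prager equivalent stress √(3·J₂) + α·I₁, clamped at 0.

    At α = 0 this reduces to the von Mises stress; α > 0 adds pressure
    sensitivity through the first stress invariant I₁ = tr(σ).
    """
    if alpha < 0:
        raise ValueError("Drucker–Prager pressure sensitivity must be non-negative")
    s = _check_symmetric(sigma)
    scalar = s.ndim == 2
    s = s.reshape(-1, 3, 3)
    i1 = np.trace(s, axis1=1, axis2=2)
    vm = von_mises(s)
    dp = np.maximum(np.atleast_1d(vm) + alpha * i1, 0.0)
    return float(dp[0]) if scalar else dp


def equivalent_stress(sigma: np.ndarray, part: np.ndarray, alpha: float = 0.0) -> np.ndarray:
    """Per-element equivalent stress: Drucker–Prager for bone parts, von Mises
    for everything else."""
    from kneefem.materials import BONE_PARTS

    sigma = np.asarray(sigma, dtype=float).reshape(-1, 3, 3)
    part = np.asarray(part).astype(str)
    out = von_mises(sigma)
    bone = np.isin(part, BONE_PARTS)
    if bone.any():
        out = np.where(bone, drucker_prager_eq(sigma, alpha), out)
    return out


#: Default colour-scale range (MPa) for exported stress maps.
STRESS_MAP_RANGE = (0.0, 5.0)


def plot_surface_field(
    points: np.ndarray,
    faces: np.ndarray,
    values: np.ndarray,
    path,
    vmin: float = STRESS_MAP_RANGE[0],
    vmax: float = STRESS_MAP_RANGE[1],
    title: str = "",
    label: str = "MPa",
) -> None:
    """Render a per-face scalar field on a (roughly horizontal) surface as a
    top-view map with the 0–5 MPa default colour range."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection

    points = np.asarray(points, float)
    faces = np.asarray(faces, int)
    polys = points[faces][:, :, :2]
    fig, ax = plt.subplots(figsize=(5, 4))
    coll = PolyCollection(polys, array=np.asarray(values, float), cmap="jet", edgecolors="none")
    coll.set_clim(vmin, vmax)
    ax.add_collection(coll)
    ax.autoscale()
    ax.set_aspect("equal")
    ax.set_xlabel("x (medial–lateral, mm)")
    ax.set_ylabel("y (anterior–posterior, mm)")
    if title:
        ax.set_title(title)
    fig.colorbar(coll, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class ContactSummary:
    """Aggregate contact quantities for one pair (units mm², N/mm², N)."""

    total_area: float
    average_pressure: float
    max_pressure: float
    resultant_force: list
    resultant_magnitude: float
    n_active: int

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_contact(result: SolveResult, pair_index: int = 0) -> ContactSummary:
    """Contact area, pressures and resultant force of one contact pair.

    Area sums the tributary areas of slave nodes whose normal traction exceeds
    ``CONTACT_TRACTION_EPS``; the average pressure is area-weighted
    (Σ|Fₙ| / Σarea); the resultant is the vector sum of nodal contact forces.
    """
    if not result.converged:
        raise ValueError("contact summary requires a converged solve")
    state = _pair_state(result, pair_index)
    fn = np.linalg.norm(state.normal_force, axis=1)
    traction = np.divide(fn, state.area, out=np.zeros_like(fn), where=state.area > 0)
    sel = traction > CONTACT_TRACTION_EPS
    area = float(state.area[sel].sum())
    total_force = state.normal_force + state.tangential_force
    resultant = total_force[sel].sum(axis=0) if sel.any() else np.zeros(3)
    avg = float(fn[sel].sum() / area) if area > 0 else 0.0
    mx = float(traction[sel].max()) if sel.any() else 0.0
    return ContactSummary(
        total_area=area,
        average_pressure=avg,
        max_pressure=mx,
        resultant_force=resultant.tolist(),
        resultant_magnitude=float(np.linalg.norm(resultant)),
        n_active=int(sel.sum()),
    )


def combine_contact(result: SolveResult, pair_indices=None) -> ContactSummary:
    """Pool several (non-tied) pairs into one joint-level summary."""
    if pair_indices is None:
        pair_indices = [s.pair_index for s in result.contact if not s.tied]
    areas, forces, fns, tractions = [], [], [], []
    for pi in pair_indices:
        state = _pair_state(result, pi)
        fn = np.linalg.norm(state.normal_force, axis=1)
        traction = np.divide(fn, state.area, out=np.zeros_like(fn), where=state.area > 0)
        sel = traction > CONTACT_TRACTION_EPS
        areas.append(state.area[sel])
        fns.append(fn[sel])
        tractions.append(traction[sel])
        forces.append((state.normal_force + state.tangential_force)[sel])
    area = float(np.concatenate(areas).sum()) if areas else 0.0
    fn_all = np.concatenate(fns) if fns else np.zeros(0)
    resultant = np.concatenate(forces).sum(axis=0) if forces else np.zeros(3)
    tr_all = np.concatenate(tractions) if tractions else np.zeros(0)
    return ContactSummary(
        total_area=area,
        average_pressure=float(fn_all.sum() / area) if area > 0 else 0.0,
        max_pressure=float(tr_all.max()) if len(tr_all) else 0.0,
        resultant_force=resultant.tolist(),
        resultant_magnitude=float(np.linalg.norm(resultant)),
        n_active=int(len(fn_all)),
    )


def _pair_state(result: SolveResult, pair_index: int) -> ContactState:
    for s in result.contact:
        if s.pair_index == pair_index:
            return s
    raise ValueError(f"no contact pair with index {pair_index}")


def compartment_split(
    result: SolveResult,
    points: np.ndarray,
    plane_point=(0.0, 0.0, 0.0),
    plane_normal=(1.0, 0.0, 0.0),
    pair_indices=None,
) -> tuple[float, float]:
    """Split the total contact force magnitude across a partition plane.

    Returns (positive-side, negative-side) sums of nodal normal-force
    magnitudes, classified by each slave node's side of the plane (medial vs
    lateral for the default X-normal plane through the joint centre).
    """
    normal = np.asarray(plane_normal, dtype=float)
    nn = np.linalg.norm(normal)
    if nn < 1e-12:
        raise ValueError("degenerate partition plane (zero normal)")
    normal = normal / nn
    origin = np.asarray(plane_point, dtype=float)
    if pair_indices is None:
        pair_indices = [s.pair_index for s in result.contact if not s.tied]
    pos = neg = 0.0
    for pi in pair_indices:
        state = _pair_state(result, pi)
        fn = np.linalg.norm(state.normal_force, axis=1)
        side = (np.asarray(points)[state.slave_nodes] - origin) @ normal
        pos += float(fn[side >= 0].sum())
        neg += float(fn[side < 0].sum())
    return pos, neg
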