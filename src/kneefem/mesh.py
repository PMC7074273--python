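"""Unstructured mesh container: tet4 solids, triangular shells, 2-node trusses.

The container is deliberately plain — numpy arrays plus named node/facet sets —
so that the generator, the material mapper and the solver can share it without
any hidden state. Units are mm throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class MeshError(ValueError):
    pass


@dataclass
class Mesh:
    """Mesh with labelled parts.

    Attributes
    ----------
    points : (n, 3) float array, mm
    tets : (m, 4) int array
        Linear tetrahedra, positively oriented.
    tet_part : (m,) str array
        Part label per tetrahedron (e.g. ``femur``, ``tibia``, ``cartilage``,
        ``meniscus``).
    tris : (s, 3) int array
        Triangular shell elements.
    tri_part : (s,) str array
    trusses : (t, 2) int array
        Two-node axial elements (ligaments / tendons).
    truss_names : list of str
        One name per truss, keying into the strain–tension law table.
    node_sets : dict name -> (k,) int array
    facet_sets : dict name -> (k, 3) int array
        Oriented boundary triangles (outward normals) used for contact and
        surface loads.
    """

    points: np.ndarray
    tets: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), dtype=int))
    tet_part: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    tris: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=int))
    tri_part: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    trusses: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=int))
    truss_names: list = field(default_factory=list)
    node_sets: dict = field(default_factory=dict)
    facet_sets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.tets = np.asarray(self.tets, dtype=int).reshape(-1, 4)
        self.tris = np.asarray(self.tris, dtype=int).reshape(-1, 3)
        self.trusses = np.asarray(self.trusses, dtype=int).reshape(-1, 2)
        self.tet_part = np.asarray(self.tet_part, dtype=object)
        self.tri_part = np.asarray(self.tri_part, dtype=object)

    # ------------------------------------------------------------ geometry
    @property
    def n_nodes(self) -> int:
        return len(self.points)

    def tet_volumes(self) -> np.ndarray:
        p = self.points
        a = p[self.tets[:, 1]] - p[self.tets[:, 0]]
        b = p[self.tets[:, 2]] - p[self.tets[:, 0]]
        c = p[self.tets[:, 3]] - p[self.tets[:, 0]]
        return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0

    def tet_centroids(self) -> np.ndarray:
        return self.points[self.tets].mean(axis=1)

    def tri_areas(self, tris: np.ndarray | None = None) -> np.ndarray:
        tris = self.tris if tris is None else tris
        p = self.points
        n = np.cross(p[tris[:, 1]] - p[tris[:, 0]], p[tris[:, 2]] - p[tris[:, 0]])
        return 0.5 * np.linalg.norm(n, axis=1)

    def part_nodes(self, part: str) -> np.ndarray:
        """Unique node ids referenced by the tets (and shells) of a part."""
        ids = [self.tets[self.tet_part == part].ravel()]
        if len(self.tri_part):
            ids.append(self.tris[self.tri_part == part].ravel())
        return np.unique(np.concatenate(ids))

    def validate(self) -> None:
        vols = self.tet_volumes()
        bad = np.where(vols <= 0)[0]
        if bad.size:
            raise MeshError(f"inverted/degenerate tetrahedra at indices {bad[:10].tolist()}")
        if not np.all(np.isfinite(self.points)):
            raise MeshError("non-finite node coordinates")

    # ---------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return {
            "points": self.points.tolist(),
            "tets": self.tets.tolist(),
            "tet_part": list(self.tet_part),
            "tris": self.tris.tolist(),
            "tri_part": list(self.tri_part),
            "trusses": self.trusses.tolist(),
            "truss_names": list(self.truss_names),
            "node_sets": {k: np.asarray(v).tolist() for k, v in self.node_sets.items()},
            "facet_sets": {k: np.asarray(v).tolist() for k, v in self.facet_sets.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Mesh":
        return cls(
            points=np.array(d["points"], dtype=float).reshape(-1, 3),
            tets=np.array(d["tets"], dtype=int).reshape(-1, 4),
            tet_part=np.array(d["tet_part"], dtype=object),
            tris=np.array(d["tris"], dtype=int).reshape(-1, 3),
            tri_part=np.array(d["tri_part"], dtype=object),
            trusses=np.array(d["trusses"], dtype=int).reshape(-1, 2),
            truss_names=list(d["truss_names"]),
            node_sets={k: np.array(v, dtype=int) for k, v in d["node_sets"].items()},
            facet_sets={k: np.array(v, dtype=int).reshape(-1, 3) for k, v in d["facet_sets"].items()},
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load_json(cls, path: str | Path) -> "Mesh":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------- builders

def box_mesh(xs: np.ndarray, ys: np.ndarray, zs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Structured tet mesh of a box from grid lines (each hex split into 6 tets).

    Returns (points, tets) with all tets positively oriented.
    """
    xs, ys, zs = (np.asarray(v, dtype=float) for v in (xs, ys, zs))
    nx, ny, nz = len(xs), len(ys), len(zs)
    if min(nx, ny, nz) < 2:
        raise MeshError("box_mesh needs at least two grid lines per axis")
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    points = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    i, j, k = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1), indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    # hex corners (local 0..7)
    c = [
        nid(i, j, k),
        nid(i + 1, j, k),
        nid(i + 1, j + 1, k),
        nid(i, j + 1, k),
        nid(i, j, k + 1),
        nid(i + 1, j, k + 1),
        nid(i + 1, j + 1, k + 1),
        nid(i, j + 1, k + 1),
    ]
    # Kuhn 6-tet split around the 0-6 diagonal
    pattern = [(0, 1, 2, 6), (0, 2, 3, 6), (0, 3, 7, 6), (0, 7, 4, 6), (0, 4, 5, 6), (0, 5, 1, 6)]
    tets = np.concatenate([np.column_stack([c[a], c[b], c[cc], c[d]]) for a, b, cc, d in pattern])

    # fix orientation where needed
    a = points[tets[:, 1]] - points[tets[:, 0]]
    b = points[tets[:, 2]] - points[tets[:, 0]]
    d = points[tets[:, 3]] - points[tets[:, 0]]
    neg = np.einsum("ij,ij->i", np.cross(a, b), d) < 0
    tets[neg, 1], tets[neg, 2] = tets[neg, 2].copy(), tets[neg, 1].copy()
    return points, tets


def grid_lines(lo: float, hi: float, target: float) -> np.ndarray:
    """Grid lines over [lo, hi] with spacing as close as possible to ``target``."""
    n = max(1, int(round((hi - lo) / target)))
    return np.linspace(lo, hi, n + 1)


def boundary_faces(tets: np.ndarray) -> np.ndarray:
    """Outward-oriented boundary triangles of a tet block.

    For a positively oriented tet (n0, n1, n2, n3) the four outward faces are
    (n1,n2,n3), (n0,n3,n2), (n0,n1,n3), (n0,n2,n1); faces shared by two tets
    cancel and are dropped.
    """
    t = tets
    faces = np.concatenate(
        [t[:, [1, 2, 3]], t[:, [0, 3, 2]], t[:, [0, 1, 3]], t[:, [0, 2, 1]]]
    )
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def merge_meshes(parts: list[tuple[np.ndarray, np.ndarray, str]]) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]:
    """Concatenate (points, tets, label) blocks with node-id offsets.

    Returns (points, tets, tet_part, offsets) where ``offsets[i]`` is the node-id
    offset applied to block i.
    """
    pts, tts, labels, offsets = [], [], [], []
    off = 0
    for p, t, lab in parts:
        offsets.append(off)
        pts.append(p)
        tts.append(t + off)
        labels.append(np.full(len(t), lab, dtype=object))
        off += len(p)
    return (
        np.concatenate(pts),
        np.concatenate(tts),
        np.concatenate(labels),
        offsets,
    )
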