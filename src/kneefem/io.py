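"""Minimal legacy-VTK (ASCII, unstructured grid) writer/reader.

Covers exactly what the pipeline exports: points, tet/tri/line cells, and
named point/cell scalar, vector or tensor fields. Floats are written with
``repr`` so a write/read cycle reproduces the arrays bit-exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_CELL_VTK_TYPE = {4: 10, 3: 5, 2: 3}  # tet4, triangle, line


def _fmt(arr: np.ndarray) -> str:
    return "\n".join(" ".join(repr(float(v)) for v in row) for row in np.atleast_2d(arr))


def write_vtk(
    path: str | Path,
    points: np.ndarray,
    cells: list[np.ndarray],
    cell_data: dict[str, np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
    title: str = "kneefem",
) -> None:
    """Write an unstructured grid.

    ``cells`` is a list of connectivity arrays (n_i, k) with k in {2, 3, 4};
    ``cell_data`` arrays are concatenated in the same block order and may be
    (n,), (n, 3) or (n, 3, 3).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    cells = [np.asarray(c, dtype=int) for c in cells if len(c)]
    ncell = sum(len(c) for c in cells)
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(points)} double",
        _fmt(points),
    ]
    size = sum(len(c) * (c.shape[1] + 1) for c in cells)
    lines.append(f"CELLS {ncell} {size}")
    for c in cells:
        k = c.shape[1]
        block = np.column_stack([np.full(len(c), k), c])
        lines.append("\n".join(" ".join(str(v) for v in row) for row in block))
    lines.append(f"CELL_TYPES {ncell}")
    lines.append("\n".join(str(_CELL_VTK_TYPE[c.shape[1]]) for c in cells for _ in range(len(c))))

    def _emit_fields(tag: str, n: int, data: dict[str, np.ndarray]) -> None:
        lines.append(f"{tag} {n}")
        for name, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.append("\n".join(repr(float(v)) for v in arr))
            elif arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines.append(_fmt(arr))
            elif arr.ndim == 3 and arr.shape[1:] == (3, 3):
                lines.append(f"TENSORS {name} double")
                lines.append(_fmt(arr.reshape(len(arr), 9)))
            else:
                raise ValueError(f"unsupported field shape for {name}: {arr.shape}")

    if cell_data:
        _emit_fields("CELL_DATA", ncell, cell_data)
    if point_data:
        _emit_fields("POINT_DATA", len(points), point_data)
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk(path: str | Path) -> dict:
    """Read a file produced by :func:`write_vtk`.

    Returns dict with keys ``points``, ``cells`` (list of arrays grouped by
    node count, in file order), ``cell_data``, ``point_data``.
    """
    tokens = Path(path).read_text().split("\n")
    out = {"points": None, "cells": [], "cell_data": {}, "point_data": {}}
    i = 0

    def words(line):
        return line.split()

    raw_cells = []
    while i < len(tokens):
        w = words(tokens[i])
        if not w:
            i += 1
            continue
        if w[0] == "POINTS":
            n = int(w[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(x) for x in tokens[i].split())
                i += 1
            out["points"] = np.array(vals).reshape(n, 3)
            continue
        if w[0] == "CELLS":
            n = int(w[1])
            i += 1
            for _ in range(n):
                row = [int(x) for x in tokens[i].split()]
                raw_cells.append(row[1:])
                i += 1
            continue
        if w[0] == "CELL_TYPES":
            n = int(w[1])
            i += n + 1
            continue
        if w[0] in ("CELL_DATA", "POINT_DATA"):
            target = "cell_data" if w[0] == "CELL_DATA" else "point_data"
            n = int(w[1])
            i += 1
            while i < len(tokens):
                w2 = words(tokens[i])
                if not w2:
                    i += 1
                    continue
                if w2[0] == "SCALARS":
                    name = w2[1]
                    i += 2  # skip LOOKUP_TABLE
                    vals = []
                    while len(vals) < n:
                        vals.extend(float(x) for x in tokens[i].split())
                        i += 1
                    out[target][name] = np.array(vals)
                elif w2[0] == "VECTORS":
                    name = w2[1]
                    i += 1
                    vals = []
                    while len(vals) < 3 * n:
                        vals.extend(float(x) for x in tokens[i].split())
                        i += 1
                    out[target][name] = np.array(vals).reshape(n, 3)
                elif w2[0] == "TENSORS":
                    name = w2[1]
                    i += 1
                    vals = []
                    while len(vals) < 9 * n:
                        vals.extend(float(x) for x in tokens[i].split())
                        i += 1
                    out[target][name] = np.array(vals).reshape(n, 3, 3)
                else:
                    break
            continue
        i += 1

    # group consecutive cells by node count
    groups: list[np.ndarray] = []
    cur: list[list[int]] = []
    for row in raw_cells:
        if cur and len(row) != len(cur[0]):
            groups.append(np.array(cur, dtype=int))
            cur = []
        cur.append(row)
    if cur:
        groups.append(np.array(cur, dtype=int))
    out["cells"] = groups
    return out
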