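"""Cellular-complex data model for 3D plant tissues.

A tissue is represented as a shared-vertex cellular complex: vertices sit at
cell-wall junctions, walls are polygonal faces (ordered vertex cycles), and
cells are closed polyhedra described as sets of wall indices.  Every wall
belongs to one cell (an outer wall, on the tissue boundary) or exactly two
cells (an inner wall shared by neighbours).

Orientation convention: the stored vertex cycle of an outer wall winds so the
right-hand normal points out of the tissue; an inner wall winds out of its
lower-index adjacent cell.  All geometric queries (volumes, validation, wall
pressures) rely on this convention, and the tissue-JSON schema requires it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MeshError",
    "BoundaryCondition",
    "TissueMesh",
    "Triangulation",
    "triangulate_wall",
    "cell_volume",
    "validate_mesh",
    "read_tissue",
    "write_tissue",
    "export_vtk",
]


class MeshError(ValueError):
    """Raised for structurally invalid tissue meshes or walls."""


@dataclass
class BoundaryCondition:
    """Kinematic constraint on a set of nodes.

    kind 'fixed' pins all three coordinates; kind 'planar' removes the motion
    component along ``normal`` (nodes slide freely in the plane), as used for
    the basal nodes of a meristem dome held in a horizontal plane.
    """

    nodes: np.ndarray
    kind: str  # 'fixed' | 'planar'
    normal: np.ndarray | None = None
    offset: float = 0.0

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=int)
        if self.kind not in ("fixed", "planar"):
            raise MeshError(f"unknown constraint kind {self.kind!r}")
        if self.kind == "planar":
            if self.normal is None:
                raise MeshError("planar constraint requires a normal")
            n = np.asarray(self.normal, dtype=float)
            nn = np.linalg.norm(n)
            if nn == 0:
                raise MeshError("planar constraint normal must be nonzero")
            self.normal = n / nn


@dataclass
class TissueMesh:
    """Shared-vertex cellular complex (vertices, walls, cells, labels)."""

    vertices: np.ndarray                      # (V, 3) float
    walls: list[np.ndarray]                   # each an ordered vertex cycle
    cells: list[np.ndarray]                   # each a set of wall indices
    region_labels: dict[int, str] = field(default_factory=dict)
    boundary: list[BoundaryCondition] = field(default_factory=list)
    cell_layer: np.ndarray | None = None      # generator metadata: radial shell index

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.walls = [np.asarray(w, dtype=int) for w in self.walls]
        self.cells = [np.asarray(c, dtype=int) for c in self.cells]
        if self.cell_layer is not None:
            self.cell_layer = np.asarray(self.cell_layer, dtype=int)
        self._wall_cells: list[tuple[int, ...]] | None = None

    # -- derived topology -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def wall_cells(self) -> list[tuple[int, ...]]:
        """For each wall, the sorted tuple of adjacent cell indices."""
        if self._wall_cells is None:
            adj: list[list[int]] = [[] for _ in self.walls]
            for ci, cell in enumerate(self.cells):
                for wi in cell:
                    adj[wi].append(ci)
            self._wall_cells = [tuple(sorted(a)) for a in adj]
        return self._wall_cells

    @property
    def wall_labels(self) -> list[str]:
        """'outer-periclinal' (boundary), 'anticlinal' (between two outermost-
        layer cells) or 'inner' for every wall."""
        layer = self.cell_layer
        outermost = int(layer.max()) if layer is not None and len(layer) else None
        labels = []
        for adj in self.wall_cells:
            if len(adj) == 1:
                labels.append("outer-periclinal")
            elif outermost is not None and all(layer[c] == outermost for c in adj):
                labels.append("anticlinal")
            else:
                labels.append("inner")
        return labels

    def wall_orientation(self, cell_index: int, wall_index: int) -> int:
        """+1 if the stored cycle of the wall points out of the given cell."""
        adj = self.wall_cells[wall_index]
        if cell_index not in adj:
            raise MeshError(f"wall {wall_index} not part of cell {cell_index}")
        return 1 if cell_index == adj[0] else -1

    def copy(self) -> "TissueMesh":
        return TissueMesh(
            self.vertices.copy(),
            [w.copy() for w in self.walls],
            [c.copy() for c in self.cells],
            dict(self.region_labels),
            [BoundaryCondition(bc.nodes.copy(), bc.kind,
                               None if bc.normal is None else bc.normal.copy(),
                               bc.offset)
             for bc in self.boundary],
            None if self.cell_layer is None else self.cell_layer.copy(),
        )


@dataclass
class Triangulation:
    """Flat-triangle tessellation of a set of walls.

    ``triangles`` is (T, 3) vertex indices in the orientation of the parent
    wall's stored cycle; ``tri_wall`` maps each triangle to its wall.
    """

    triangles: np.ndarray
    tri_wall: np.ndarray


def triangulate_wall(wall: Sequence[int]) -> list[tuple[int, int, int]]:
    """Fan-triangulate a polygonal wall from its lowest-index vertex.

    Deterministic: the cycle is rotated so the smallest vertex index leads,
    then triangles (v0, v_i, v_{i+1}) are emitted in cycle order.  An n-gon
    yields n-2 triangles whose orientation matches the cycle.
    """
    w = np.asarray(wall, dtype=int)
    if len(w) < 3:
        raise MeshError(f"wall has fewer than 3 vertices: {w.tolist()}")
    if len(np.unique(w)) != len(w):
        raise MeshError(f"wall has repeated vertices: {w.tolist()}")
    cyc = np.roll(w, -int(np.argmin(w)))
    return [(int(cyc[0]), int(cyc[i]), int(cyc[i + 1]))
            for i in range(1, len(cyc) - 1)]


def triangulate(mesh: TissueMesh, wall_indices: Iterable[int] | None = None) -> Triangulation:
    """Triangulate a subset of walls (default: all walls)."""
    if wall_indices is None:
        wall_indices = range(len(mesh.walls))
    tris, owner = [], []
    for wi in wall_indices:
        for t in triangulate_wall(mesh.walls[wi]):
            tris.append(t)
            owner.append(wi)
    return Triangulation(np.asarray(tris, dtype=int).reshape(-1, 3),
                         np.asarray(owner, dtype=int))


def _cell_oriented_triangles(mesh: TissueMesh, cell_index: int) -> np.ndarray:
    """All triangles of a cell, oriented outward per the storage convention."""
    tris = []
    for wi in mesh.cells[cell_index]:
        sign = mesh.wall_orientation(cell_index, wi)
        for (a, b, c) in triangulate_wall(mesh.walls[wi]):
            tris.append((a, b, c) if sign > 0 else (a, c, b))
    return np.asarray(tris, dtype=int)


def _closure_violations(mesh: TissueMesh, cell_index: int) -> list[str]:
    """Edge-incidence check: each edge of a closed oriented cell surface must
    appear exactly once in each direction."""
    edges: dict[tuple[int, int], int] = {}
    for wi in mesh.cells[cell_index]:
        sign = mesh.wall_orientation(cell_index, wi)
        w = mesh.walls[wi]
        cyc = w if sign > 0 else w[::-1]
        for i in range(len(cyc)):
            e = (int(cyc[i]), int(cyc[(i + 1) % len(cyc)]))
            edges[e] = edges.get(e, 0) + 1
    out = []
    for (a, b), cnt in edges.items():
        if cnt != 1 or edges.get((b, a), 0) != 1:
            out.append(f"cell {cell_index} not closed at edge ({a},{b})")
    return out


def cell_volume(mesh: TissueMesh, cell_index: int,
                positions: np.ndarray | None = None) -> float:
    """Signed divergence-theorem volume of a cell; positive when the cell is
    closed and outward-oriented."""
    x = mesh.vertices if positions is None else np.asarray(positions, float)
    tris = _cell_oriented_triangles(mesh, cell_index)
    a, b, c = x[tris[:, 0]], x[tris[:, 1]], x[tris[:, 2]]
    return float(np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0)


def cell_volumes(mesh: TissueMesh, positions: np.ndarray | None = None) -> np.ndarray:
    return np.array([cell_volume(mesh, ci, positions) for ci in range(len(mesh.cells))])


def validate_mesh(mesh: TissueMesh) -> list[str]:
    """Check the TissueMesh invariants; return a report of violations.

    An empty report means: every wall is a simple polygon with >=3 distinct
    vertices and valid indices, wall/cell adjacency degree is 1 or 2, every
    cell is closed and consistently oriented, and all cell volumes are
    strictly positive.
    """
    report: list[str] = []
    nv = mesh.n_vertices
    for wi, w in enumerate(mesh.walls):
        if len(w) < 3:
            report.append(f"wall {wi} has fewer than 3 vertices")
        elif len(np.unique(w)) != len(w):
            report.append(f"wall {wi} has repeated vertices")
        if len(w) and (w.min() < 0 or w.max() >= nv):
            report.append(f"wall {wi} references invalid vertex index")
    if report:
        return report
    for wi, adj in enumerate(mesh.wall_cells):
        if len(adj) not in (1, 2):
            report.append(f"wall {wi} has adjacency degree {len(adj)}")
    for ci in range(len(mesh.cells)):
        closure = _closure_violations(mesh, ci)
        if closure:
            report.append("cell not closed: " + closure[0])
            continue
        vol = cell_volume(mesh, ci)
        if not vol > 0:
            report.append(f"cell {ci} has non-positive volume {vol:.3g}")
    for bi, bc in enumerate(mesh.boundary):
        if len(bc.nodes) and (bc.nodes.min() < 0 or bc.nodes.max() >= nv):
            report.append(f"boundary condition {bi} references invalid node index")
    return report


# -- tissue-JSON I/O -------------------------------------------------------

def write_tissue(mesh: TissueMesh, path) -> None:
    """Serialize to the tissue-JSON schema (exact round-trip)."""
    doc = {
        "vertices": mesh.vertices.tolist(),
        "walls": [w.tolist() for w in mesh.walls],
        "cells": [c.tolist() for c in mesh.cells],
        "region_labels": {str(k): v for k, v in mesh.region_labels.items()},
        "boundary": [
            {"nodes": bc.nodes.tolist(), "kind": bc.kind,
             **({"normal": bc.normal.tolist(), "offset": bc.offset}
                if bc.kind == "planar" else {})}
            for bc in mesh.boundary
        ],
    }
    if mesh.cell_layer is not None:
        doc["cell_layer"] = mesh.cell_layer.tolist()
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_tissue(path) -> TissueMesh:
    """Read the tissue-JSON schema; raise MeshError naming any missing field."""
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("vertices", "walls", "cells"):
        if key not in doc:
            raise MeshError(f"tissue-JSON missing required field {key!r}")
    boundary = []
    for b in doc.get("boundary", []):
        if "nodes" not in b or "kind" not in b:
            raise MeshError("tissue-JSON boundary entry missing 'nodes' or 'kind'")
        boundary.append(BoundaryCondition(
            np.asarray(b["nodes"], int), b["kind"],
            np.asarray(b["normal"], float) if "normal" in b else None,
            float(b.get("offset", 0.0))))
    return TissueMesh(
        np.asarray(doc["vertices"], float),
        [np.asarray(w, int) for w in doc["walls"]],
        [np.asarray(c, int) for c in doc["cells"]],
        {int(k): v for k, v in doc.get("region_labels", {}).items()},
        boundary,
        np.asarray(doc["cell_layer"], int) if "cell_layer" in doc else None,
    )


def export_vtk(mesh: TissueMesh, positions: np.ndarray | None, path,
               cell_data: dict[str, np.ndarray] | None = None,
               triangulation: Triangulation | None = None) -> Triangulation:
    """Write a legacy-ASCII VTK unstructured grid of the wall triangulation.

    ``cell_data`` maps array names (e.g. 'strain_norm', 'stress_norm',
    'region_id') to per-triangle scalars.  Returns the triangulation used, so
    callers can build matching per-triangle arrays.
    """
    x = mesh.vertices if positions is None else np.asarray(positions, float)
    tri = triangulation if triangulation is not None else triangulate(mesh)
    t = tri.triangles
    lines = ["# vtk DataFile Version 3.0", "morphomech tissue", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {len(x)} double"]
    lines += [" ".join(f"{v:.17g}" for v in p) for p in x]
    lines.append(f"CELLS {len(t)} {4 * len(t)}")
    lines += [f"3 {a} {b} {c}" for a, b, c in t]
    lines.append(f"CELL_TYPES {len(t)}")
    lines += ["5"] * len(t)
    if cell_data:
        lines.append(f"CELL_DATA {len(t)}")
        for name, arr in cell_data.items():
            arr = np.asarray(arr, float).ravel()
            if len(arr) != len(t):
                raise MeshError(f"cell-data array {name!r} has wrong length")
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.17g}" for v in arr]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return tri
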