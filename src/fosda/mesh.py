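"""Triangle-mesh data model and mesh / vertex-map I/O.

A :class:`TriangleMesh` is the carrier of all finite-element structure in
the package: a template cortical (or synthetic spherical) surface and the
subject surfaces are all closed, oriented triangle meshes whose vertices
are in one-to-one correspondence across subjects.  A :class:`VertexFunction`
is a piecewise-linear scalar field on such a mesh, stored by its values at
the vertices (the coefficients in the linear finite-element basis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

__all__ = [
    "TriangleMesh",
    "VertexFunction",
    "read_mesh",
    "write_mesh",
    "read_vertex_function",
    "write_vertex_function",
    "save_map_collection",
    "load_map_collection",
]

#: triangles with area below this fraction of (bbox diagonal)^2 are rejected
DEGENERATE_AREA_FRACTION = 1e-12


@dataclass(frozen=True)
class TriangleMesh:
    """An oriented triangle mesh embedded in R^3.

    Parameters
    ----------
    vertices : (s, 3) float array
        Vertex coordinates in mm.
    faces : (t, 3) int array
        0-based vertex indices, counter-clockwise seen from outside.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=float))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be an (s, 3) array")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be a (t, 3) array")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite vertex coordinates")
        if f.min(initial=0) < 0 or f.max(initial=-1) >= len(v):
            raise ValueError("face indices out of range [0, s)")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    # -- basic descriptors -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def bbox_diagonal(self) -> float:
        span = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(span))

    def face_areas(self) -> np.ndarray:
        p = self.vertices[self.faces]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def face_normals(self) -> np.ndarray:
        p = self.vertices[self.faces]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        norms = np.linalg.norm(cross, axis=1, keepdims=True)
        return cross / np.where(norms > 0, norms, 1.0)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def edges(self) -> np.ndarray:
        """Undirected edges as a sorted (e, 2) array of unique vertex pairs."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_faces

    def is_closed(self) -> bool:
        """Every undirected edge shared by exactly two faces."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        _, counts = np.unique(np.sort(e, axis=1), axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def is_oriented(self) -> bool:
        """Each interior edge traversed once in each direction (consistent CCW)."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 1))

    # -- validation --------------------------------------------------------
    def validate(self, require_closed: bool = False) -> None:
        """Check mesh invariants; raise ``ValueError`` on violation.

        Degenerate triangles (area below ``1e-12 * bbox_diagonal**2``) are a
        hard error — silently skipping them would corrupt the differential
        penalty downstream.  Orientation is checked, never repaired.
        """
        tol = DEGENERATE_AREA_FRACTION * self.bbox_diagonal ** 2
        areas = self.face_areas()
        bad = np.nonzero(areas <= tol)[0]
        if bad.size:
            raise ValueError(f"degenerate triangle at face index {bad[0]} "
                             f"(area {areas[bad[0]]:.3e} <= tol {tol:.3e})")
        if require_closed:
            if not self.is_closed():
                raise ValueError("mesh is not closed: an edge is not shared "
                                 "by exactly 2 faces")
            if not self.is_oriented():
                raise ValueError("mesh orientation is inconsistent")
            if self.euler_characteristic() != 2:
                raise ValueError("Euler characteristic V-E+F != 2 "
                                 "(not a topological sphere)")

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        """Same connectivity, new vertex positions."""
        return TriangleMesh(vertices=vertices, faces=self.faces)


@dataclass(frozen=True)
class VertexFunction:
    """Piecewise-linear scalar field on a mesh, one value per vertex."""

    values: np.ndarray
    mesh: TriangleMesh = field(compare=False)

    def __post_init__(self) -> None:
        vals = np.ascontiguousarray(np.asarray(self.values, dtype=float)).ravel()
        if len(vals) != self.mesh.n_vertices:
            raise ValueError(
                f"value count {len(vals)} != vertex count {self.mesh.n_vertices}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite vertex values")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# I/O — OFF and PLY through trimesh; vertex maps as headered delimited text.
# ---------------------------------------------------------------------------

def read_mesh(path: str | Path) -> TriangleMesh:
    """Read an OFF or PLY mesh, preserving the vertex order exactly.

    Vertex order carries the cross-subject correspondence, so no merging,
    deduplication or reordering is ever applied on load.
    """
    tm = trimesh.load(str(path), process=False, maintain_order=True)
    if not isinstance(tm, trimesh.Trimesh):
        raise ValueError(f"{path} does not contain a single triangle mesh")
    return TriangleMesh(vertices=np.asarray(tm.vertices),
                        faces=np.asarray(tm.faces))


def write_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    """Write a mesh to OFF or PLY (format chosen from the file suffix)."""
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                         process=False)
    tm.export(str(path))


def read_vertex_function(path: str | Path, mesh: TriangleMesh) -> VertexFunction:
    """Read a vertex map from headered delimited text (vertex_index, value)."""
    df = pd.read_csv(path, sep=r"\s+|,|\t", engine="python")
    if "vertex_index" not in df.columns or "value" not in df.columns:
        raise ValueError(f"{path}: expected columns 'vertex_index' and 'value'")
    values = np.full(mesh.n_vertices, np.nan)
    values[df["vertex_index"].to_numpy(dtype=int)] = df["value"].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError(f"{path}: map does not cover every vertex")
    return VertexFunction(values=values, mesh=mesh)


def write_vertex_function(fn: VertexFunction, path: str | Path) -> None:
    df = pd.DataFrame({"vertex_index": np.arange(len(fn)),
                       "value": fn.values})
    df.to_csv(path, sep="\t", index=False)


def save_map_collection(path: str | Path, maps: np.ndarray,
                        labels: np.ndarray | None = None) -> None:
    """Packed container for a full dataset of vertex maps (n x s) + labels."""
    payload = {"maps": np.asarray(maps, dtype=float)}
    if labels is not None:
        payload["labels"] = np.asarray(labels)
    np.savez_compressed(str(path), **payload)


def load_map_collection(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    with np.load(str(path)) as data:
        maps = data["maps"]
        labels = data["labels"] if "labels" in data else None
    return maps, labels
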