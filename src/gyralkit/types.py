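"""Core mesh containers shared by every stage of the pipeline.

All containers are thin, validated wrappers around numpy arrays.  Vertex
indices are 0-based everywhere.  Coordinates are dimensionless: surfaces
destined for comparison are normalized by half their longitudinal (x)
extent, so a brain-like object spans x in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


def _as_points(a, name: str) -> np.ndarray:
    a = np.ascontiguousarray(a, dtype=np.float64)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"{name} must be (n, 3), got {a.shape}")
    if not np.isfinite(a).all():
        raise ValueError(f"{name} contains non-finite coordinates")
    return a


def _as_index(a, width: int, n_vertices: int, name: str) -> np.ndarray:
    a = np.ascontiguousarray(a, dtype=np.int64)
    if a.ndim != 2 or a.shape[1] != width:
        raise ValueError(f"{name} must be (n, {width}), got {a.shape}")
    if a.size and (a.min() < 0 or a.max() >= n_vertices):
        raise ValueError(f"{name} has vertex indices outside [0, {n_vertices})")
    return a


@dataclass
class TriSurface:
    """Oriented triangle mesh.

    Faces are counterclockwise when seen from outside (along the outward
    normal).  The mesh may be closed (a whole brain surface) or open
    (a dissected hemisphere with one boundary loop).
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = _as_points(self.vertices, "vertices")
        self.faces = _as_index(self.faces, 3, len(self.vertices), "faces")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges_unique(self) -> np.ndarray:
        """Unique undirected edges, sorted pairs, shape (E, 2)."""
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges_unique()) + self.n_faces

    def face_normals(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(n, axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def boundary_edges(self) -> np.ndarray:
        """Edges used by exactly one face (undirected, sorted pairs)."""
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts == 1]

    def boundary_vertices(self) -> np.ndarray:
        be = self.boundary_edges()
        return np.unique(be) if len(be) else np.empty(0, dtype=np.int64)

    def copy(self) -> "TriSurface":
        return TriSurface(self.vertices.copy(), self.faces.copy())


@dataclass
class TetVolume:
    """Tetrahedral solid: the simulation domain for the growth model.

    Tets are oriented so the signed volume
    det(v1-v0, v2-v0, v3-v0) / 6 is positive.
    """

    vertices: np.ndarray
    tets: np.ndarray

    def __post_init__(self):
        self.vertices = _as_points(self.vertices, "vertices")
        self.tets = _as_index(self.tets, 4, len(self.vertices), "tets")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        v = self.vertices
        t = self.tets
        d1 = v[t[:, 1]] - v[t[:, 0]]
        d2 = v[t[:, 2]] - v[t[:, 0]]
        d3 = v[t[:, 3]] - v[t[:, 0]]
        return np.einsum("ij,ij->i", np.cross(d1, d2), d3) / 6.0

    def boundary_surface(self) -> "TriSurface":
        """Outward-oriented boundary triangles (faces used by one tet).

        Vertex indices are preserved (no compaction), so per-vertex fields
        on the volume restrict directly to the surface.
        """
        faces = boundary_faces_of_tets(self.tets)
        return TriSurface(self.vertices, faces)

    def copy(self) -> "TetVolume":
        return TetVolume(self.vertices.copy(), self.tets.copy())


def boundary_faces_of_tets(tets: np.ndarray) -> np.ndarray:
    """Faces of a tet mesh incident to exactly one tet, outward-oriented.

    For a positively oriented tet (v0, v1, v2, v3) the four outward faces
    are (v1,v2,v3), (v0,v3,v2), (v0,v1,v3), (v0,v2,v1).
    """
    t = tets
    tri = np.concatenate(
        [
            t[:, [1, 2, 3]],
            t[:, [0, 3, 2]],
            t[:, [0, 1, 3]],
            t[:, [0, 2, 1]],
        ]
    )
    key = np.sort(tri, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return np.ascontiguousarray(tri[counts[inv] == 1])


@dataclass
class LandmarkCurve:
    """Ordered vertex-index polyline on a TriSurface (a synthetic sulcus).

    Consecutive vertices must share a mesh edge; vertices do not repeat.
    """

    vertex_path: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.vertex_path = np.ascontiguousarray(self.vertex_path, dtype=np.int64)
        if self.vertex_path.ndim != 1 or len(self.vertex_path) < 2:
            raise ValueError("vertex_path must be a 1-D index array with >= 2 entries")
        if len(np.unique(self.vertex_path)) != len(self.vertex_path):
            raise ValueError("landmark path repeats a vertex")

    def validate_on(self, surface: TriSurface) -> None:
        p = self.vertex_path
        if p.max() >= surface.n_vertices:
            raise ValueError("landmark path references a vertex outside the surface")
        edges = {tuple(e) for e in surface.edges_unique()}
        for a, b in zip(p[:-1], p[1:]):
            if (min(a, b), max(a, b)) not in edges:
                raise ValueError(f"landmark path step {a}->{b} is not a mesh edge")


@dataclass
class ScalarField:
    """One real value per vertex of an associated surface."""

    values: np.ndarray
    surface_id: str = ""

    def __post_init__(self):
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if not np.isfinite(self.values).all():
            raise ValueError("field contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ValidationReport:
    """Topological audit of a TriSurface, by explicit counting."""

    euler_characteristic: int
    boundary_loop_count: int
    is_edge_manifold: bool
    is_oriented: bool
    genus_if_closed: Optional[int] = None
    is_vertex_manifold: bool = True
    n_vertices: int = 0
    n_edges: int = 0
    n_faces: int = 0
    n_degenerate_faces: int = 0

    @property
    def disk_mappable(self) -> bool:
        """True iff the surface is a simply connected open disk."""
        return (
            self.euler_characteristic == 1
            and self.boundary_loop_count == 1
            and self.is_edge_manifold
            and self.is_vertex_manifold
            and self.is_oriented
        )

    def to_dict(self) -> dict:
        d = {
            "euler_characteristic": self.euler_characteristic,
            "boundary_loop_count": self.boundary_loop_count,
            "is_edge_manifold": self.is_edge_manifold,
            "is_vertex_manifold": self.is_vertex_manifold,
            "is_oriented": self.is_oriented,
            "genus_if_closed": self.genus_if_closed,
            "n_vertices": self.n_vertices,
            "n_edges": self.n_edges,
            "n_faces": self.n_faces,
            "n_degenerate_faces": self.n_degenerate_faces,
            "disk_mappable": self.disk_mappable,
        }
        return d
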