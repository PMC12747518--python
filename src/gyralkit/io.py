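"""Mesh I/O, topological validation, hemisphere dissection, normalization.

Supported formats
-----------------
surfaces   OFF, ASCII PLY (with optional per-vertex scalar), STL
tet meshes legacy ASCII VTK unstructured grids, TetGen .node/.ele pairs
fields     CSV with header ``vertex_index,value``
landmarks  JSON: list of ``{"name": ..., "vertex_path": [...]}``

OFF and STL go through trimesh.  PLY is read and written natively because
the comparison pipeline stores per-vertex scalar fields (shape index,
rescaled mean curvature) as double-precision vertex properties, which
must round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh

from .types import (
    LandmarkCurve,
    ScalarField,
    TetVolume,
    TriSurface,
    ValidationReport,
)

__all__ = [
    "read_mesh",
    "write_mesh",
    "validate_surface",
    "cut_hemisphere",
    "normalize_halflength",
]


# ---------------------------------------------------------------- writers


def _write_ply(surface: TriSurface, path: Path, field: ScalarField | None = None):
    v, f = surface.vertices, surface.faces
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(v)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        if field is not None:
            if len(field) != len(v):
                raise ValueError("field length does not match vertex count")
            fh.write("property double quality\n")
        fh.write(f"element face {len(f)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        if field is None:
            for p in v:
                fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        else:
            for p, q in zip(v, field.values):
                fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g} {q:.17g}\n")
        for tri in f:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")


def _read_ply(path: Path):
    with open(path) as fh:
        if fh.readline().strip() != "ply":
            raise ValueError(f"{path}: not a PLY file")
        n_vert = n_face = 0
        vert_props: list[str] = []
        element = None
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "format":
                if tok[1] != "ascii":
                    raise ValueError(f"{path}: only ASCII PLY is supported")
            elif tok[0] == "element":
                element = tok[1]
                if element == "vertex":
                    n_vert = int(tok[2])
                elif element == "face":
                    n_face = int(tok[2])
            elif tok[0] == "property" and element == "vertex" and tok[1] != "list":
                vert_props.append(tok[2])
            elif tok[0] == "end_header":
                break
        for axis in ("x", "y", "z"):
            if axis not in vert_props:
                raise ValueError(f"{path}: vertex property {axis} missing")
        rows = [fh.readline().split() for _ in range(n_vert)]
        data = np.asarray(rows, dtype=np.float64)
        if data.shape != (n_vert, len(vert_props)):
            raise ValueError(f"{path}: malformed vertex block")
        cols = {p: data[:, i] for i, p in enumerate(vert_props)}
        verts = np.column_stack([cols["x"], cols["y"], cols["z"]])
        faces = []
        for _ in range(n_face):
            tok = fh.readline().split()
            if int(tok[0]) != 3:
                raise ValueError(f"{path}: non-triangular face")
            faces.append([int(tok[1]), int(tok[2]), int(tok[3])])
        faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    extra = [p for p in vert_props if p not in ("x", "y", "z")]
    field = ScalarField(cols[extra[0]]) if extra else None
    return TriSurface(verts, faces), field


def _write_vtk_tets(volume: TetVolume, path: Path):
    v, t = volume.vertices, volume.tets
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 2.0\ngyralkit tet mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(v)} double\n")
        for p in v:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        fh.write(f"CELLS {len(t)} {5 * len(t)}\n")
        for tet in t:
            fh.write(f"4 {tet[0]} {tet[1]} {tet[2]} {tet[3]}\n")
        fh.write(f"CELL_TYPES {len(t)}\n")
        fh.write("\n".join(["10"] * len(t)) + "\n")


def _read_vtk_tets(path: Path) -> TetVolume:
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    verts = tets = None
    for line in it:
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "POINTS":
            n = int(tok[1])
            flat: list[float] = []
            while len(flat) < 3 * n:
                flat.extend(float(x) for x in next(it).split())
            verts = np.asarray(flat, dtype=np.float64).reshape(n, 3)
        elif tok[0] == "CELLS":
            n = int(tok[1])
            cells = []
            for _ in range(n):
                row = [int(x) for x in next(it).split()]
                if row[0] != 4:
                    raise ValueError(f"{path}: cell with {row[0]} nodes; expected tets")
                cells.append(row[1:])
            tets = np.asarray(cells, dtype=np.int64)
    if verts is None or tets is None:
        raise ValueError(f"{path}: missing POINTS or CELLS section")
    return TetVolume(verts, tets)


def _read_tetgen(node_path: Path) -> TetVolume:
    """TetGen .node/.ele pair; pass the .node path."""
    node_path = Path(node_path)
    ele_path = node_path.with_suffix(".ele")

    def data_lines(p):
        for line in Path(p).read_text().splitlines():
            line = line.split("#")[0].strip()
            if line:
                yield line.split()

    it = data_lines(node_path)
    n, dim = (int(x) for x in next(it)[:2])
    if dim != 3:
        raise ValueError(f"{node_path}: expected 3-D nodes")
    rows = [next(it) for _ in range(n)]
    ids = np.asarray([int(r[0]) for r in rows])
    verts = np.asarray([[float(x) for x in r[1:4]] for r in rows])
    base = ids.min()  # TetGen may index from 0 or 1
    it = data_lines(ele_path)
    m = int(next(it)[0])
    tets = np.asarray(
        [[int(x) - base for x in next(it)[1:5]] for _ in range(m)], dtype=np.int64
    )
    return TetVolume(verts, tets)


def _write_tetgen(volume: TetVolume, node_path: Path):
    """TetGen .node/.ele pair (0-based), written next to each other."""
    node_path = Path(node_path)
    with open(node_path, "w") as fh:
        fh.write(f"{volume.n_vertices} 3 0 0\n")
        for i, p in enumerate(volume.vertices):
            fh.write(f"{i} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
    with open(node_path.with_suffix(".ele"), "w") as fh:
        fh.write(f"{volume.n_tets} 4 0\n")
        for i, t in enumerate(volume.tets):
            fh.write(f"{i} {t[0]} {t[1]} {t[2]} {t[3]}\n")


def write_mesh(obj, path, fmt: str | None = None, field: ScalarField | None = None):
    """Write a mesh object; format inferred from the extension if omitted.

    Pairings: TriSurface -> OFF/PLY/STL; TetVolume -> VTK;
    ScalarField -> CSV (or piggybacked on a PLY via ``field=``);
    list[LandmarkCurve] -> JSON; ValidationReport -> JSON.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if isinstance(obj, TriSurface):
        if fmt == "ply":
            _write_ply(obj, path, field)
        elif fmt in ("off", "stl"):
            m = trimesh.Trimesh(obj.vertices, obj.faces, process=False)
            out = m.export(file_type=fmt)
            mode = "wb" if isinstance(out, bytes) else "w"
            with open(path, mode) as fh:
                fh.write(out)
        else:
            raise ValueError(f"unsupported surface format: {fmt}")
    elif isinstance(obj, TetVolume):
        if fmt == "vtk":
            _write_vtk_tets(obj, path)
        elif fmt == "node":
            _write_tetgen(obj, path)
        else:
            raise ValueError(f"unsupported tet format: {fmt}")
    elif isinstance(obj, ScalarField):
        if fmt != "csv":
            raise ValueError(f"unsupported field format: {fmt}")
        with open(path, "w") as fh:
            fh.write("vertex_index,value\n")
            for i, x in enumerate(obj.values):
                fh.write(f"{i},{x:.17g}\n")
    elif isinstance(obj, list) and all(isinstance(c, LandmarkCurve) for c in obj):
        if fmt != "json":
            raise ValueError(f"unsupported landmark format: {fmt}")
        payload = [
            {"name": c.name, "vertex_path": c.vertex_path.tolist()} for c in obj
        ]
        Path(path).write_text(json.dumps(payload, indent=1))
    elif isinstance(obj, ValidationReport):
        Path(path).write_text(json.dumps(obj.to_dict(), indent=1))
    else:
        raise ValueError(f"cannot write object of type {type(obj).__name__}")


def read_mesh(path, kind: str | None = None, surface: TriSurface | None = None):
    """Read a mesh object, inferring the kind from the file extension.

    kind: surface | tet | field | landmarks (optional override; a PLY with
    kind='field' returns its per-vertex scalar instead of the surface).
    Passing ``surface`` validates landmark files against it (index range
    and edge connectivity) at read time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = path.suffix.lstrip(".").lower()
    if ext == "ply":
        surface, fld = _read_ply(path)
        if kind == "field":
            if fld is None:
                raise ValueError(f"{path}: no per-vertex scalar property")
            return fld
        return surface
    if ext in ("off", "stl"):
        m = trimesh.load(str(path), file_type=ext, process=(ext == "stl"))
        if ext == "stl":
            m.merge_vertices(merge_tex=True, merge_norm=True)
        return TriSurface(
            np.asarray(m.vertices, dtype=np.float64),
            np.asarray(m.faces, dtype=np.int64),
        )
    if ext == "vtk":
        return _read_vtk_tets(path)
    if ext == "node":
        return _read_tetgen(path)
    if ext == "csv":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        order = np.argsort(data[:, 0])
        return ScalarField(data[order, 1])
    if ext == "json":
        payload = json.loads(path.read_text())
        curves = [
            LandmarkCurve(np.asarray(c["vertex_path"], dtype=np.int64), c.get("name", ""))
            for c in payload
        ]
        if surface is not None:
            for c in curves:
                c.validate_on(surface)
        return curves
    raise ValueError(f"unsupported file extension: {ext}")


# ----------------------------------------------------- validation & cuts


def validate_surface(surface: TriSurface) -> ValidationReport:
    """Topological audit by explicit counting; never raises on bad input.

    A surface is disk-mappable (simply connected open surface) iff it is
    edge-manifold, consistently oriented, has Euler characteristic 1 and
    exactly one boundary loop.
    """
    f = surface.faces
    v = surface.vertices
    n_deg = int((surface.face_areas() < 1e-14).sum())

    directed = f[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    und = np.sort(directed, axis=1)
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    n_edges = len(uniq)
    euler = len(v) - n_edges + len(f)
    is_manifold = bool((counts <= 2).all())

    # oriented: no directed edge repeats (each interior edge is traversed
    # once in each direction)
    d_uniq, d_counts = np.unique(directed, axis=0, return_counts=True)
    is_oriented = bool((d_counts == 1).all()) and is_manifold

    b_edges = uniq[counts == 1]
    n_loops = 0
    if len(b_edges):
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        bv = np.unique(b_edges)
        remap = {int(x): i for i, x in enumerate(bv)}
        i0 = [remap[int(a)] for a in b_edges[:, 0]]
        i1 = [remap[int(b)] for b in b_edges[:, 1]]
        g = coo_matrix(
            (np.ones(len(b_edges)), (i0, i1)), shape=(len(bv), len(bv))
        )
        n_loops, _ = connected_components(g, directed=False)

    genus = None
    if len(b_edges) == 0 and is_manifold and is_oriented:
        genus = (2 - euler) // 2

    # vertex-manifold: the faces around each vertex form a single fan
    # (connected via shared edges incident to that vertex)
    is_vmanifold = True
    if is_manifold:
        incident: dict[int, list[int]] = {}
        for fi, tri in enumerate(f):
            for vi in tri:
                incident.setdefault(int(vi), []).append(fi)
        edge_faces: dict[tuple[int, int], list[int]] = {}
        for fi, tri in enumerate(f):
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                edge_faces.setdefault((min(a, b), max(a, b)), []).append(fi)
        for vi, flist in incident.items():
            if len(flist) <= 1:
                continue
            # union-find over the vertex's incident faces
            parent = {fi: fi for fi in flist}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for tri_idx in flist:
                tri = f[tri_idx]
                for other in tri:
                    if other == vi:
                        continue
                    key = (min(vi, other), max(vi, other))
                    for neighbor in edge_faces.get(key, ()):
                        if neighbor != tri_idx and neighbor in parent:
                            parent[find(neighbor)] = find(tri_idx)
            roots = {find(fi) for fi in flist}
            if len(roots) > 1:
                is_vmanifold = False
                break

    return ValidationReport(
        euler_characteristic=int(euler),
        boundary_loop_count=int(n_loops),
        is_edge_manifold=is_manifold,
        is_vertex_manifold=is_vmanifold,
        is_oriented=is_oriented,
        genus_if_closed=genus,
        n_vertices=len(v),
        n_edges=n_edges,
        n_faces=len(f),
        n_degenerate_faces=n_deg,
    )


def cut_hemisphere(
    surface: TriSurface, plane_point=(0.0, 0.0, 0.0), plane_normal=(1.0, 0.0, 0.0)
) -> TriSurface:
    """Dissect a closed surface by a plane, keeping the positive side.

    Triangles crossing the plane are split exactly at the edge-plane
    intersections; vertices exactly on the plane belong to the kept side.
    The result of cutting a closed genus-0 surface is an open disk with a
    single boundary loop along the cut.
    """
    p0 = np.asarray(plane_point, dtype=np.float64)
    n = np.asarray(plane_normal, dtype=np.float64)
    n = n / np.linalg.norm(n)
    v = surface.vertices
    s = (v - p0) @ n
    scale = np.abs(s).max() or 1.0
    eps = 1e-12 * scale
    s = np.where(np.abs(s) < eps, 0.0, s)
    if (s <= 0).all() or (s >= 0).all():
        if (s < 0).all():
            raise ValueError("plane does not intersect the surface")

    new_verts = list(v)
    cut_cache: dict[tuple[int, int], int] = {}

    def intersection(i: int, j: int) -> int:
        key = (min(i, j), max(i, j))
        if key not in cut_cache:
            t = s[i] / (s[i] - s[j])
            cut_cache[key] = len(new_verts)
            new_verts.append(v[i] + t * (v[j] - v[i]))
        return cut_cache[key]

    out_faces = []
    for tri in surface.faces:
        si = s[tri]
        if (si >= 0).all():
            if (si == 0).all():
                continue  # degenerate sliver exactly in the plane
            out_faces.append(list(tri))
            continue
        if (si <= 0).all():
            continue
        poly = []
        for k in range(3):
            i, j = tri[k], tri[(k + 1) % 3]
            if s[i] >= 0:
                poly.append(int(i))
            if s[i] * s[j] < 0:
                poly.append(intersection(int(i), int(j)))
        if len(poly) >= 3:
            for k in range(1, len(poly) - 1):
                out_faces.append([poly[0], poly[k], poly[k + 1]])

    verts = np.asarray(new_verts)
    faces = np.asarray(out_faces, dtype=np.int64)
    used = np.unique(faces)
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    result = TriSurface(verts[used], remap[faces])

    report = validate_surface(result)
    if report.boundary_loop_count > 1:
        raise ValueError(
            f"cut produced {report.boundary_loop_count} boundary loops "
            "(plane grazes the surface or the input is not genus 0)"
        )
    return result


def normalize_halflength(obj):
    """Rescale coordinates by half the longitudinal (x) extent.

    Brain surfaces are compared in units of L = L_x / 2, so after
    normalization every object spans an x-extent of exactly 2.  Callers
    must pre-align the longitudinal axis with x.  Idempotent.
    """
    if not isinstance(obj, (TriSurface, TetVolume)):
        raise TypeError("normalize_halflength expects a TriSurface or TetVolume")
    x = obj.vertices[:, 0]
    extent = x.max() - x.min()
    if extent <= 0:
        raise ValueError("zero longitudinal extent")
    out = obj.copy()
    out.vertices = obj.vertices * (2.0 / extent)
    return out
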