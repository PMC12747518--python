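"""Seeded generators for all input geometry.

Everything downstream of this module (growth simulation, morphometry,
disk mapping, similarity) is exercised on meshes produced here: analytic
curvature patches, icospheres, smooth brain-like ellipsoidal solids and
synthetic sulcal landmark curves.  Generators are pure functions of their
arguments, including the seed, so pipelines are reproducible bit for bit.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from scipy.special import sph_harm_y

from .types import LandmarkCurve, TetVolume, TriSurface

__all__ = [
    "make_icosphere",
    "make_quadric_patch",
    "make_brainlike_solid",
    "make_landmark_curves",
    "make_slab",
]


def make_slab(shape=(20, 10, 6), extent=(2.0, 1.0, 0.6), z_grade: float = 1.0) -> TetVolume:
    """Structured tetrahedral slab (Kuhn 6-tet split of each cube cell).

    A flat bilayer fixture: grow a surface layer on the +z face and the
    slab wrinkles or creases past the buckling threshold.  The split is
    conforming across neighboring cells.  ``z_grade`` > 1 concentrates
    layers toward the top (+z) face where the growing film needs
    resolution.
    """
    nx, ny, nz = shape
    lx, ly, lz = extent
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    frac = np.linspace(0, 1, nz + 1)
    zs = lz * (1.0 - (1.0 - frac) ** z_grade)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    idx = np.arange(len(verts)).reshape(nx + 1, ny + 1, nz + 1)

    # Kuhn: six tets per cube along the 000 -> 111 diagonal, one per
    # permutation of the axis order
    from itertools import permutations

    corner = lambda di, dj, dk: idx[di : di + nx, dj : dj + ny, dk : dk + nz].ravel()
    c = {(a, b, d): corner(a, b, d) for a in (0, 1) for b in (0, 1) for d in (0, 1)}
    tets = []
    for perm in permutations(range(3)):
        p = [0, 0, 0]
        path = [tuple(p)]
        for ax in perm:
            p[ax] = 1
            path.append(tuple(p))
        tets.append(np.stack([c[q] for q in path], axis=1))
    tets = np.concatenate(tets)
    vol = TetVolume(verts, tets)
    sv = vol.tet_volumes()
    flip = sv < 0
    if flip.any():
        t = vol.tets.copy()
        t[flip] = t[flip][:, [0, 1, 3, 2]]
        vol = TetVolume(verts, t)
    return vol


def make_icosphere(subdivisions: int, radius: float = 1.0) -> TriSurface:
    """Closed genus-0 sphere by icosahedron subdivision.

    Every vertex lies exactly at distance ``radius`` from the origin;
    faces number 20 * 4**subdivisions.
    """
    if not 0 <= subdivisions <= 7:
        raise ValueError("subdivisions must be in [0, 7]")
    if radius <= 0:
        raise ValueError("radius must be positive")
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = np.asarray(m.vertices, dtype=np.float64)
    # re-project: trimesh guarantees unit length only approximately
    v = radius * v / np.linalg.norm(v, axis=1, keepdims=True)
    return TriSurface(v, np.asarray(m.faces, dtype=np.int64))


def make_quadric_patch(
    a: float, b: float, halfwidth: float = 0.5, resolution: int = 32
) -> TriSurface:
    """Open graph patch z = (a*x^2 + b*y^2) / 2 over a square.

    At the center the principal curvatures are exactly (a, b), so the
    nine sign patterns of (a, b) realize every shape-index class from
    cup (both negative) through saddle to cap (both positive).  Faces are
    oriented with the outward normal on the -z side, so a > 0 reads as an
    outward-convex (gyral) ridge.
    """
    if resolution < 8:
        raise ValueError("resolution must be >= 8")
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    x = np.linspace(-halfwidth, halfwidth, resolution)
    xx, yy = np.meshgrid(x, x, indexing="ij")
    zz = 0.5 * (a * xx**2 + b * yy**2)
    verts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    idx = np.arange(resolution * resolution).reshape(resolution, resolution)
    q00 = idx[:-1, :-1].ravel()
    q10 = idx[1:, :-1].ravel()
    q01 = idx[:-1, 1:].ravel()
    q11 = idx[1:, 1:].ravel()
    # outward normal on the -z side: the graph bends away from it, so the
    # signed principal curvatures at the center are exactly (a, b)
    faces = np.concatenate(
        [np.column_stack([q00, q11, q10]), np.column_stack([q00, q01, q11])]
    )
    return TriSurface(verts, faces)


def _real_sh_field(
    dirs: np.ndarray, n_modes: int, rng: np.random.Generator
) -> np.ndarray:
    """Seeded band-limited random field on the sphere, max-normalized to 1.

    A mixture of real spherical harmonics of degree 1..n_modes with
    N(0, 1/(2l+1)) coefficients: smooth, isotropic in expectation, and
    genus-preserving for small amplitudes.
    """
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])
    f = np.zeros(len(dirs))
    for l in range(1, n_modes + 1):
        scale = 1.0 / np.sqrt(2 * l + 1)
        for m in range(0, l + 1):
            y = sph_harm_y(l, m, theta, phi)
            if m == 0:
                f += rng.normal(0.0, scale) * y.real
            else:
                f += rng.normal(0.0, scale) * np.sqrt(2.0) * y.real
                f += rng.normal(0.0, scale) * np.sqrt(2.0) * y.imag
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def _prism_layers_to_tets(
    n_ring: int, faces: np.ndarray, n_layers: int, center_index: int
) -> np.ndarray:
    """Conforming tetrahedralization of concentric scaled shells.

    Layer k occupies vertex ids [k*n_ring, (k+1)*n_ring); each boundary
    face extrudes inward into a prism per shell, split into 3 tets with
    the shared-quad diagonal anchored at the smaller vertex id so that
    neighboring prisms agree; the innermost shell closes onto the center
    vertex with one tet per face.
    """
    tets = []
    for k in range(n_layers - 1):
        lo = faces + k * n_ring
        hi = faces + (k + 1) * n_ring
        for tri_lo, tri_hi in ((lo, hi),):
            a, b, c = tri_lo[:, 0], tri_lo[:, 1], tri_lo[:, 2]
            # rotate each bottom triangle so its smallest id comes first
            order = np.argmin(np.column_stack([a, b, c]), axis=1)
            bot = np.column_stack([a, b, c])
            top = tri_hi
            for r in (1, 2):
                rot = order == r
                bot[rot] = np.roll(bot[rot], -r, axis=1)
                top[rot] = np.roll(top[rot], -r, axis=1)
            v0, v1, v2 = bot[:, 0], bot[:, 1], bot[:, 2]
            v3, v4, v5 = top[:, 0], top[:, 1], top[:, 2]
            pick = np.minimum(v1, v5) < np.minimum(v2, v4)
            t = np.empty((len(v0), 3, 4), dtype=np.int64)
            t[pick, 0] = np.column_stack([v0, v1, v2, v5])[pick]
            t[pick, 1] = np.column_stack([v0, v1, v5, v4])[pick]
            t[pick, 2] = np.column_stack([v0, v4, v5, v3])[pick]
            t[~pick, 0] = np.column_stack([v0, v1, v2, v4])[~pick]
            t[~pick, 1] = np.column_stack([v0, v4, v2, v5])[~pick]
            t[~pick, 2] = np.column_stack([v0, v4, v5, v3])[~pick]
            tets.append(t.reshape(-1, 4))
    inner = faces + (n_layers - 1) * n_ring
    cone = np.column_stack(
        [inner, np.full(len(inner), center_index, dtype=np.int64)]
    )
    tets.append(cone)
    return np.concatenate(tets)


def make_brainlike_solid(
    seed: int,
    semi_axes=(1.0, 0.8, 0.7),
    n_modes: int = 4,
    amplitude: float = 0.05,
    target_edge: float = 0.08,
    shell_fractions=None,
) -> TetVolume:
    """Smooth genus-0 brain-like solid: a perturbed ellipsoid tet mesh.

    The boundary is an ellipsoid with the given semi-axes (longitudinal
    axis first, by convention the x axis), modulated radially by a seeded
    band-limited spherical-harmonic field of relative amplitude
    ``amplitude`` (< 0.2 keeps the surface star-shaped and genus 0).
    The interior is meshed by extruding the boundary tessellation inward
    through concentric shells graded toward the surface — fine where the
    stiff growing layer folds, coarse in the bulk — closed by a cone of
    tets at the center.

    Parameters
    ----------
    target_edge : float
        Upper bound for boundary edge lengths; sets the icosphere
        subdivision level.
    shell_fractions : sequence of float, optional
        Decreasing radial fractions in (0, 1] for the shell interfaces,
        starting at 1.0 (the boundary).  Default grades from the surface
        inward with spacing growing from roughly ``target_edge``.
    """
    semi_axes = np.asarray(semi_axes, dtype=np.float64)
    if semi_axes.shape != (3,) or (semi_axes <= 0).any():
        raise ValueError("semi_axes must be three positive lengths")
    if not 0 <= amplitude < 0.2:
        raise ValueError("amplitude must be in [0, 0.2)")

    # pick the subdivision level meeting the edge-length bound
    for sub in range(1, 8):
        sphere = make_icosphere(sub, 1.0)
        scaled = sphere.vertices * semi_axes
        e = scaled[sphere.edges_unique()]
        max_edge = np.linalg.norm(e[:, 0] - e[:, 1], axis=1).max()
        if max_edge <= target_edge:
            break
    else:
        raise ValueError(f"target_edge={target_edge} needs more than 7 subdivisions")

    rng = np.random.default_rng(seed)
    dirs = sphere.vertices
    radial = np.ones(len(dirs))
    if amplitude > 0 and n_modes >= 1:
        radial = 1.0 + amplitude * _real_sh_field(dirs, n_modes, rng)
    boundary = dirs * semi_axes * radial[:, None]

    if shell_fractions is None:
        shell_fractions = _default_shell_fractions(target_edge / semi_axes.min())
    fr = np.asarray(shell_fractions, dtype=np.float64)
    if fr[0] != 1.0 or (np.diff(fr) >= 0).any() or (fr <= 0).any():
        raise ValueError("shell_fractions must start at 1.0 and strictly decrease in (0, 1]")

    layers = [boundary * f for f in fr]
    verts = np.concatenate(layers + [np.zeros((1, 3))])
    center = len(verts) - 1
    tets = _prism_layers_to_tets(len(boundary), sphere.faces.copy(), len(fr), center)

    vol = TetVolume(verts, tets)
    sv = vol.tet_volumes()
    flip = sv < 0
    if flip.any():
        t = vol.tets.copy()
        t[flip] = t[flip][:, [0, 1, 3, 2]]
        vol = TetVolume(verts, t)
        sv = vol.tet_volumes()
    if (sv <= 0).any():
        raise RuntimeError(
            f"tetrahedralization failure: {int((sv <= 0).sum())} degenerate tets "
            f"(min signed volume {sv.min():.3e}); try a smaller amplitude or target_edge"
        )
    return vol


def _default_shell_fractions(rel_edge: float) -> np.ndarray:
    """Shell interfaces graded from the boundary inward.

    Spacing starts near the relative surface edge length and grows by 1.6x
    per shell until the remaining core (closed by the central cone) is
    reached.
    """
    fr = [1.0]
    step = max(rel_edge, 0.02)
    while fr[-1] - step > 0.45:
        fr.append(fr[-1] - step)
        step *= 1.6
    return np.asarray(fr)


def _surface_graph(surface: TriSurface) -> csr_matrix:
    e = surface.edges_unique()
    w = np.linalg.norm(
        surface.vertices[e[:, 0]] - surface.vertices[e[:, 1]], axis=1
    )
    n = surface.n_vertices
    g = csr_matrix(
        (np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
        shape=(n, n),
    )
    return g


def _dijkstra_path(graph: csr_matrix, src: int, dst: int, blocked: np.ndarray):
    g = graph.copy()
    if blocked.any():
        keep = ~blocked
        keep[[src, dst]] = True
        mask = keep[g.indices]
        g.data = np.where(mask, g.data, np.inf)
    dist, pred = dijkstra(
        g, directed=False, indices=src, return_predecessors=True
    )
    if not np.isfinite(dist[dst]):
        return None
    path = [dst]
    while path[-1] != src:
        p = pred[path[-1]]
        if p < 0:
            return None
        path.append(int(p))
    return np.asarray(path[::-1], dtype=np.int64)


def make_landmark_curves(
    surface: TriSurface,
    n_curves: int = 3,
    seed: int = 0,
    min_separation: float = 0.2,
    max_retries: int = 200,
) -> list[LandmarkCurve]:
    """Synthetic sulcal landmarks: disjoint shortest paths on the mesh.

    Endpoint pairs are drawn uniformly from the vertices (with rejection
    until the Euclidean endpoint gap exceeds 2 * min_separation); each
    curve is the graph shortest path on edge lengths, avoiding all
    vertices within min_separation of previously placed curves, which
    enforces pairwise curve separation by construction.  On open surfaces
    the boundary vertices are avoided: sulcal landmarks are interior
    features and the disk registration pins the boundary to the circle.
    """
    if n_curves < 1:
        raise ValueError("n_curves must be >= 1")
    rng = np.random.default_rng(seed)
    graph = _surface_graph(surface)
    verts = surface.vertices
    n = surface.n_vertices
    blocked = np.zeros(n, dtype=bool)
    blocked[surface.boundary_vertices()] = True
    curves: list[LandmarkCurve] = []
    for ci in range(n_curves):
        placed = False
        for _ in range(max_retries):
            s, t = rng.integers(0, n, size=2)
            if s == t or blocked[s] or blocked[t]:
                continue
            if np.linalg.norm(verts[s] - verts[t]) < 2 * min_separation:
                continue
            path = _dijkstra_path(graph, int(s), int(t), blocked)
            if path is None:
                continue
            if blocked[path].any():
                continue
            curves.append(LandmarkCurve(path, name=f"curve_{ci}"))
            # block everything within min_separation of the new curve
            d, _ = cKDTree(verts[path]).query(verts)
            blocked |= d < min_separation
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place landmark curve {ci} with separation "
                f"{min_separation} after {max_retries} retries"
            )
    return curves
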