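"""Disk parameterization and landmark-matched quasi-conformal maps.

A dissected hemisphere is a simply connected open surface; it is flattened
onto the closed unit disk by a boundary-to-circle harmonic map followed by
Beltrami correction passes that push the parameterization toward
conformality.  Two parameterized disks are then registered by a
quasi-conformal map whose Beltrami coefficient is kept below 1 in
magnitude (orientation preserved, bounded angle distortion) while soft
landmark constraints align corresponding sulcal curves.  Scalar fields
are pulled back through the composed chain g2^{-1} o f12 o g1 by
barycentric interpolation on the target disk.

The Beltrami coefficient of a piecewise-linear map f = u + iv is the
per-face complex ratio mu = (df/dz~)/(df/dz); |mu| < 1 iff the face keeps
its orientation, mu = 0 iff the map is conformal on that face.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve
from scipy.spatial import cKDTree

from .io import validate_surface
from .types import LandmarkCurve, ScalarField, TriSurface

__all__ = [
    "DiskParam",
    "QCMap",
    "disk_conformal",
    "beltrami_coefficient",
    "linear_beltrami_solve",
    "landmark_qc_map",
    "pullback_field",
]


@dataclass
class DiskParam:
    """Parameterization of an open surface over the closed unit disk."""

    uv: np.ndarray  # (N, 2)
    faces: np.ndarray
    boundary_loop: np.ndarray  # ordered vertex indices on the unit circle
    surface_id: str = ""
    mean_abs_beltrami: float = float("nan")

    @property
    def n_vertices(self) -> int:
        return len(self.uv)


@dataclass
class QCMap:
    """Quasi-conformal map between two parameterized disks.

    ``image[v]`` is the position in the target disk of source vertex v;
    the map is piecewise linear over the source triangulation.
    """

    image: np.ndarray  # (N, 2)
    source_faces: np.ndarray
    beltrami_abs: np.ndarray  # per-face |mu|
    landmark_residual: float = float("nan")
    landmark_weight: float = float("nan")


# ------------------------------------------------------------ primitives


def _ordered_boundary_loop(surface: TriSurface) -> np.ndarray:
    """Boundary vertices ordered by walking directed boundary edges in
    face orientation; starts at the smallest boundary vertex index."""
    f = surface.faces
    directed = f[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    und = np.sort(directed, axis=1)
    uniq, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    on_boundary = counts[inv] == 1
    bdir = directed[on_boundary]
    nxt = {int(a): int(b) for a, b in bdir}
    if not nxt:
        raise ValueError("surface has no boundary")
    start = min(nxt)
    loop = [start]
    while True:
        n = nxt[loop[-1]]
        if n == start:
            break
        loop.append(n)
        if len(loop) > len(nxt) + 1:
            raise ValueError("boundary is not a single simple loop")
    return np.asarray(loop, dtype=np.int64)


def _flatten_faces(surface: TriSurface) -> np.ndarray:
    """Isometric per-face 2D coordinates (T, 3, 2): p0 at origin, p1 on
    the +x axis, p2 in the upper half plane."""
    v = surface.vertices[surface.faces]
    e1 = v[:, 1] - v[:, 0]
    e2 = v[:, 2] - v[:, 0]
    l1 = np.linalg.norm(e1, axis=1)
    x2 = np.einsum("ij,ij->i", e2, e1) / np.maximum(l1, 1e-300)
    y2 = np.linalg.norm(np.cross(e1, e2), axis=1) / np.maximum(l1, 1e-300)
    out = np.zeros((len(v), 3, 2))
    out[:, 1, 0] = l1
    out[:, 2, 0] = x2
    out[:, 2, 1] = y2
    return out


def _pl_gradients(domain: np.ndarray, faces: np.ndarray | None = None):
    """Shape-function gradients and areas of a 2-D triangulation.

    ``domain`` is (T, 3, 2) per-face coordinates (pass faces=None), or
    (N, 2) vertex coordinates with ``faces`` (T, 3).
    Returns (gx, gy, area): per-face (3,) gradient coefficients such that
    (d/dx) u = sum_i gx[t, i] u_i on face t.
    """
    if faces is not None:
        tri = domain[faces]
    else:
        tri = domain
    x = tri[:, :, 0]
    y = tri[:, :, 1]
    area2 = (x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0]) - (x[:, 2] - x[:, 0]) * (
        y[:, 1] - y[:, 0]
    )
    area2 = np.where(np.abs(area2) < 1e-300, 1e-300, area2)
    gx = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    gy = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    return gx / area2[:, None], gy / area2[:, None], area2 / 2.0


def _beltrami_from_gradients(gx, gy, faces, image: np.ndarray) -> np.ndarray:
    u = image[:, 0][faces]
    v = image[:, 1][faces]
    ux = np.einsum("ti,ti->t", gx, u)
    uy = np.einsum("ti,ti->t", gy, u)
    vx = np.einsum("ti,ti->t", gx, v)
    vy = np.einsum("ti,ti->t", gy, v)
    fz = 0.5 * ((ux + vy) + 1j * (vx - uy))
    fzbar = 0.5 * ((ux - vy) + 1j * (vx + uy))
    fz = np.where(np.abs(fz) < 1e-300, 1e-300, fz)
    return fzbar / fz


def beltrami_coefficient(
    source_uv: np.ndarray, target_uv: np.ndarray, faces: np.ndarray
) -> np.ndarray:
    """Per-face complex Beltrami coefficient of the PL map source -> target.

    mu = (df/dz~)/(df/dz); identity and similarities give mu = 0, and
    |mu| < 1 exactly when the face keeps its orientation.
    """
    source_uv = np.asarray(source_uv, dtype=np.float64)
    target_uv = np.asarray(target_uv, dtype=np.float64)
    gx, gy, area = _pl_gradients(source_uv, faces)
    if (np.abs(area) < 1e-300).any():
        raise ValueError("degenerate source triangle")
    return _beltrami_from_gradients(gx, gy, faces, target_uv)


def surface_beltrami(surface: TriSurface, uv: np.ndarray) -> np.ndarray:
    """Beltrami coefficient of the parameterization S -> uv, measured in
    per-face isometric coordinates of the 3-D surface."""
    flat = _flatten_faces(surface)
    gx, gy, _ = _pl_gradients(flat)
    return _beltrami_from_gradients(gx, gy, surface.faces, uv)


def _lbs_matrix(domain_uv, faces, mu):
    """Hermitian normal matrix of the least-squares Beltrami energy
    E(f) = sum_t area_t |(f_zbar)_t - mu_t (f_z)_t|^2 over complex
    per-vertex values f.  Its null space is exactly the discrete
    solutions of the Beltrami equation f_zbar = mu f_z."""
    gx, gy, area = _pl_gradients(domain_uv, faces)
    a = np.abs(area)
    # per-face complex derivative coefficients: f_z = sum_i Dz[i] f_i
    Dz = 0.5 * (gx - 1j * gy)
    Dzb = 0.5 * (gx + 1j * gy)
    r = Dzb - mu[:, None] * Dz  # residual row per face
    n = len(domain_uv)
    rows, cols, vals = [], [], []
    for i in range(3):
        for j in range(3):
            rows.append(faces[:, i])
            cols.append(faces[:, j])
            vals.append(a * np.conj(r[:, i]) * r[:, j])
    return coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()


def linear_beltrami_solve(
    domain_uv: np.ndarray,
    faces: np.ndarray,
    target_mu: np.ndarray,
    constraint_idx: np.ndarray,
    constraint_pos: np.ndarray,
    soft_idx: np.ndarray | None = None,
    soft_pos: np.ndarray | None = None,
    soft_weight: float = 0.0,
) -> np.ndarray:
    """Reconstruct the map with prescribed per-face Beltrami coefficient.

    Minimizes the least-squares Beltrami residual subject to hard point
    constraints (eliminated) and optional soft (penalty) point
    constraints.  Constant mu with two pinned vertices recovers the
    corresponding affine map exactly.  Returns per-vertex 2-D positions.
    """
    target_mu = np.asarray(target_mu, dtype=np.complex128)
    if (np.abs(target_mu) >= 1.0).any():
        raise ValueError("|target_mu| must be < 1")
    if len(np.atleast_1d(constraint_idx)) < 2:
        raise ValueError("at least two point constraints are required")
    n = len(domain_uv)
    K = _lbs_matrix(domain_uv, faces, target_mu)
    rhs = np.zeros(n, dtype=np.complex128)
    if soft_idx is not None and len(soft_idx):
        pen = coo_matrix(
            (np.full(len(soft_idx), soft_weight), (soft_idx, soft_idx)),
            shape=(n, n),
        )
        K = K + pen.tocsr()
        rhs[soft_idx] += soft_weight * (soft_pos[:, 0] + 1j * soft_pos[:, 1])
    fixed_val = np.asarray(constraint_pos, dtype=np.float64)
    fixed_c = fixed_val[:, 0] + 1j * fixed_val[:, 1]
    interior = np.ones(n, dtype=bool)
    interior[constraint_idx] = False
    full = np.zeros(n, dtype=np.complex128)
    full[constraint_idx] = fixed_c
    Kii = K[interior][:, interior]
    Kib = K[interior][:, ~interior]
    b = rhs[interior] - Kib @ full[~interior]
    if Kii.shape[0]:
        xi = spsolve(Kii.tocsc(), b)
        if np.isnan(xi).any():
            raise ValueError("linear Beltrami system is singular")
        full[interior] = xi
    return np.column_stack([full.real, full.imag])


# ------------------------------------------------------- parameterization


def _tutte_disk(surface: TriSurface, loop: np.ndarray) -> np.ndarray:
    """Embedding of the surface over the disk with mean-value weights and
    arclength-proportional circular boundary (flip-free by Tutte)."""
    v = surface.vertices
    n = surface.n_vertices
    # boundary positions
    pts = v[loop]
    seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    s = np.r_[0.0, np.cumsum(seg[:-1])]
    theta = 2.0 * np.pi * s / seg.sum()
    bpos = np.column_stack([np.cos(theta), np.sin(theta)])

    # mean-value weights: w_ij = (tan(a/2) + tan(b/2)) / |e_ij| with a, b
    # the angles at i adjacent to edge ij
    f = surface.faces
    w_entries = {}
    for i, j, k in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        pi = v[f[:, i]]
        pj = v[f[:, j]]
        pk = v[f[:, k]]
        e_ij = pj - pi
        e_ik = pk - pi
        dot = np.einsum("ij,ij->i", e_ij, e_ik)
        crs = np.linalg.norm(np.cross(e_ij, e_ik), axis=1)
        ang = np.arctan2(crs, dot)
        tan_half = np.tan(ang / 2.0)
        lij = np.linalg.norm(e_ij, axis=1)
        lik = np.linalg.norm(e_ik, axis=1)
        # angle at i contributes to both edges (i, j) and (i, k)
        for dst, ln in ((f[:, j], lij), (f[:, k], lik)):
            key = (f[:, i], dst)
            arr = tan_half / np.maximum(ln, 1e-300)
            w_entries.setdefault("rows", []).append(f[:, i])
            w_entries.setdefault("cols", []).append(dst)
            w_entries.setdefault("vals", []).append(arr)
    rows = np.concatenate(w_entries["rows"])
    cols = np.concatenate(w_entries["cols"])
    vals = np.concatenate(w_entries["vals"])
    W = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    d = np.asarray(W.sum(axis=1)).ravel()
    from scipy.sparse import diags

    L = diags(d) - W
    interior = np.ones(n, dtype=bool)
    interior[loop] = False
    uv = np.zeros((n, 2))
    uv[loop] = bpos
    Lii = L[interior][:, interior]
    Lib = L[interior][:, ~interior]
    uv[interior] = spsolve(Lii.tocsc(), -Lib @ uv[~interior])
    return uv


def _flipped_count(uv: np.ndarray, faces: np.ndarray) -> int:
    _, _, area = _pl_gradients(uv, faces)
    return int((area <= 0).sum())


def disk_conformal(
    surface: TriSurface, n_correction_passes: int = 3
) -> DiskParam:
    """Flatten a simply connected open surface onto the closed unit disk.

    Pipeline: arclength-proportional circular boundary, mean-value
    (Tutte) harmonic interior — an embedding, so no flipped parameter
    triangles — then Beltrami correction passes: the conformality defect
    mu of S -> uv is transported to the disk and cancelled by a linear
    Beltrami solve with the boundary held on the circle, with backtracking
    if a pass would flip a triangle.  The achieved mean |mu| is reported
    on the result.
    """
    report = validate_surface(surface)
    if not report.disk_mappable:
        raise ValueError(
            "surface is not disk-mappable: "
            f"chi={report.euler_characteristic}, "
            f"loops={report.boundary_loop_count}, "
            f"manifold={report.is_edge_manifold}, oriented={report.is_oriented}"
        )
    loop = _ordered_boundary_loop(surface)
    uv = _tutte_disk(surface, loop)
    if _flipped_count(uv, surface.faces):
        # Tutte guarantees an embedding only up to numerical conditioning
        raise RuntimeError("initial disk embedding has flipped triangles")

    flat = _flatten_faces(surface)
    gx, gy, _ = _pl_gradients(flat)
    for _ in range(n_correction_passes):
        mu = _beltrami_from_gradients(gx, gy, surface.faces, uv)
        # correction map c: D -> D with mu_c = -mu * fz/conj(fz), so that
        # mu_{c o f} vanishes to first order
        u = uv[:, 0][surface.faces]
        w = uv[:, 1][surface.faces]
        ux = np.einsum("ti,ti->t", gx, u)
        uy = np.einsum("ti,ti->t", gy, u)
        vx = np.einsum("ti,ti->t", gx, w)
        vy = np.einsum("ti,ti->t", gy, w)
        fz = 0.5 * ((ux + vy) + 1j * (vx - uy))
        fz = np.where(np.abs(fz) < 1e-300, 1e-300, fz)
        mu_c = -mu * fz / np.conj(fz)
        mag = np.abs(mu_c)
        mu_c = np.where(mag > 0.9, mu_c * 0.9 / np.maximum(mag, 1e-300), mu_c)
        uv_new = linear_beltrami_solve(
            uv, surface.faces, mu_c, loop, uv[loop]
        )
        # backtrack toward the previous embedding if the pass flips faces
        step = 1.0
        while step > 1e-3 and _flipped_count(
            uv + step * (uv_new - uv), surface.faces
        ):
            step *= 0.5
        cand = uv + step * (uv_new - uv)
        if _flipped_count(cand, surface.faces):
            break
        old_mean = float(np.abs(mu).mean())
        new_mu = _beltrami_from_gradients(gx, gy, surface.faces, cand)
        if float(np.abs(new_mu).mean()) >= old_mean:
            break
        uv = cand

    mu = _beltrami_from_gradients(gx, gy, surface.faces, uv)
    return DiskParam(
        uv=uv,
        faces=surface.faces.copy(),
        boundary_loop=loop,
        mean_abs_beltrami=float(np.abs(mu).mean()),
    )


# --------------------------------------------------------- landmark match


def _resample_polyline(points: np.ndarray, n_samples: int) -> np.ndarray:
    """Points at n_samples equally spaced normalized-arclength fractions."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.r_[0.0, np.cumsum(seg)]
    total = s[-1]
    if total <= 0:
        return np.repeat(points[:1], n_samples, axis=0)
    t = np.linspace(0.0, total, n_samples)
    out = np.empty((n_samples, points.shape[1]))
    for c in range(points.shape[1]):
        out[:, c] = np.interp(t, s, points[:, c])
    return out


def _arclength_fractions(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.r_[0.0, np.cumsum(seg)]
    return s / max(s[-1], 1e-300)


def landmark_qc_map(
    D1: DiskParam,
    D2: DiskParam,
    lm1: list[LandmarkCurve],
    lm2: list[LandmarkCurve],
    tol: float = 1e-3,
    n_samples: int = 20,
    max_rounds: int = 12,
    mu_clamp: float = 0.95,
) -> QCMap:
    """Landmark-aligned quasi-conformal map f12 : D1 -> D2.

    Each source landmark curve (vertices of D1) is matched to the point at
    the same normalized arclength fraction on the corresponding target
    curve (soft constraints, weight increased geometrically until the
    resampled landmark mismatch drops below tol).  The unit-circle
    boundary maps to itself (boundary vertices held fixed), and the
    per-face Beltrami magnitude is clamped at ``mu_clamp`` so the map
    never folds.  If the tolerance cannot be reached without exceeding
    the clamp, the achieved mismatch is reported on the result.
    """
    if len(lm1) != len(lm2):
        raise ValueError("landmark curve counts differ")
    uv1 = D1.uv
    faces = D1.faces

    loop = D1.boundary_loop
    on_boundary = np.zeros(D1.n_vertices, dtype=bool)
    on_boundary[loop] = True

    src_idx_list = []
    tgt_pos_list = []
    for c1, c2 in zip(lm1, lm2):
        p1 = uv1[c1.vertex_path]
        p2 = D2.uv[c2.vertex_path]
        frac = _arclength_fractions(p1)
        tgt_s = _arclength_fractions(p2)
        tgt = np.empty((len(frac), 2))
        for c in range(2):
            tgt[:, c] = np.interp(frac, tgt_s, p2[:, c])
        # boundary-pinned vertices cannot follow a landmark target
        free = ~on_boundary[c1.vertex_path]
        if free.sum() < 2:
            raise ValueError(
                f"landmark curve '{c1.name}' lies on the disk boundary"
            )
        src_idx_list.append(c1.vertex_path[free])
        tgt_pos_list.append(tgt[free])
    src_idx = np.concatenate(src_idx_list)
    tgt_pos = np.concatenate(tgt_pos_list)
    f = uv1.copy()
    weight = 10.0
    residual = np.inf
    for _ in range(max_rounds):
        mu = beltrami_coefficient(uv1, f, faces)
        mag = np.abs(mu)
        mu = np.where(mag > mu_clamp, mu * mu_clamp / np.maximum(mag, 1e-300), mu)
        f_new = linear_beltrami_solve(
            uv1, faces, mu, loop, uv1[loop],
            soft_idx=src_idx, soft_pos=tgt_pos, soft_weight=weight,
        )
        step = 1.0
        while step > 1e-3 and _flipped_count(
            f + step * (f_new - f), faces
        ):
            step *= 0.5
        cand = f + step * (f_new - f)
        if _flipped_count(cand, faces):
            break
        f = cand
        residual = _landmark_residual(f, src_idx_list, tgt_pos_list, n_samples)
        if residual < tol:
            break
        weight *= 4.0

    mu_final = np.abs(beltrami_coefficient(uv1, f, faces))
    return QCMap(
        image=f,
        source_faces=faces,
        beltrami_abs=mu_final,
        landmark_residual=float(residual),
        landmark_weight=weight,
    )


def _landmark_residual(f, src_idx_list, tgt_pos_list, n_samples) -> float:
    worst = 0.0
    for idx, tgt in zip(src_idx_list, tgt_pos_list):
        rs_map = _resample_polyline(f[idx], n_samples)
        rs_tgt = _resample_polyline(tgt, n_samples)
        worst = max(worst, float(np.linalg.norm(rs_map - rs_tgt, axis=1).max()))
    return worst


# -------------------------------------------------------------- pullback


def pullback_field(
    field_on_S2: ScalarField,
    qc_image: np.ndarray,
    D2: DiskParam,
) -> ScalarField:
    """Pull a field on S2 back to S1 vertices through g2^{-1} o f12 o g1.

    ``qc_image`` holds, for each S1 vertex, its position in the D2 disk
    (i.e. f12(g1(v))).  The value is barycentric-interpolated over the
    containing D2 parameter triangle; points that spill outside the disk
    numerically are projected onto the boundary circle first.
    """
    if len(field_on_S2) != D2.n_vertices:
        raise ValueError("field length does not match D2 vertex count")
    import matplotlib.tri as mtri

    pts = np.asarray(qc_image, dtype=np.float64).copy()
    r = np.linalg.norm(pts, axis=1)
    outside = r > 1.0
    pts[outside] *= ((1.0 - 1e-9) / r[outside])[:, None]

    try:
        tri = mtri.Triangulation(D2.uv[:, 0], D2.uv[:, 1], D2.faces)
        finder = tri.get_trifinder()
        fidx = finder(pts[:, 0], pts[:, 1])
    except RuntimeError:
        # degenerate or folded parameter triangles: locate by nearest
        # centroid instead (exact when the true triangle is found)
        cent = D2.uv[D2.faces].mean(axis=1)
        _, fidx = cKDTree(cent).query(pts)
        fidx = np.asarray(fidx, dtype=np.int64)
    missing = fidx < 0
    if missing.any():
        # shrink slightly toward the centroid and retry (boundary slivers)
        for shrink in (1e-7, 1e-5, 1e-3):
            p2 = pts[missing] * (1.0 - shrink)
            fidx2 = finder(p2[:, 0], p2[:, 1])
            pts[missing] = np.where((fidx2 >= 0)[:, None], p2, pts[missing])
            fidx[missing] = np.where(fidx2 >= 0, fidx2, fidx[missing])
            missing = fidx < 0
            if not missing.any():
                break
    if missing.any():
        # last resort: nearest parameter triangle by centroid
        cent = D2.uv[D2.faces].mean(axis=1)
        _, nearest = cKDTree(cent).query(pts[missing])
        fidx[missing] = nearest

    tris = D2.faces[fidx]
    a = D2.uv[tris[:, 0]]
    b = D2.uv[tris[:, 1]]
    c = D2.uv[tris[:, 2]]
    det = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (
        b[:, 1] - a[:, 1]
    )
    det = np.where(np.abs(det) < 1e-300, 1e-300, det)
    w1 = (
        (pts[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
        - (c[:, 0] - a[:, 0]) * (pts[:, 1] - a[:, 1])
    ) / det
    w2 = (
        (b[:, 0] - a[:, 0]) * (pts[:, 1] - a[:, 1])
        - (pts[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    ) / det
    w0 = 1.0 - w1 - w2
    w = np.clip(np.stack([w0, w1, w2], axis=1), 0.0, 1.0)
    w /= w.sum(axis=1, keepdims=True)
    vals = field_on_S2.values[tris]
    return ScalarField(np.einsum("ij,ij->i", w, vals))
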