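"""Differential-growth simulator for cortical folding.

The brain is modeled as a soft neo-Hookean solid whose superficial layer
(gray matter) grows tangentially relative to the bulk (white matter).
Growth enters through the multiplicative morphoelastic decomposition
F = A G with growth tensor

    G = sqrt(g) I + (1 - sqrt(g)) n (x) n,

which expands area by the factor g in the plane perpendicular to the
local surface direction n and leaves the n direction unstretched.  The
stored elastic energy per unit reference volume is the modestly
compressible neo-Hookean form

    W = mu/2 (J_A^{-2/3} tr(A^T A) - 3) + K/2 (J_A - 1)^2,

with J_A = det A and bulk modulus K = 5 mu by default.  Both the shear
modulus and the growth ratio follow a sigmoid profile in the reference
distance d to the cortical surface,

    q(d) = q_w + (q_g - q_w) / (1 + exp(10 (d/h - 1))),

where h is the cortical thickness, optionally shrinking linearly in the
normalized growth time t.  The mismatch between the grown layer and the
substrate puts the cortex under compression; past a critical growth the
layer creases and folds, forming gyri and sulci.

The relaxation is an explicit quasi-static energy minimization
(dynamic relaxation with kinetic damping) with a vertex-pair self-contact
penalty on the boundary surface so folded gyri cannot interpenetrate.
Growth is applied in small increments with relaxation between them,
either continuously from the initial geometry or step-wise, where at
prescribed stage times the current (folded) geometry is adopted as the
new stress-free reference before growth resumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree

from ._kernels import contact_energy_forces, elastic_energy_forces
from .types import TetVolume, TriSurface, boundary_faces_of_tets

__all__ = [
    "GrowthConfig",
    "SimState",
    "boundary_distance_field",
    "sigmoid_profile",
    "growth_tensor",
    "neo_hookean_energy",
    "total_energy_and_forces",
    "relax",
    "run_growth",
    "extract_boundary_surface",
]


@dataclass
class GrowthConfig:
    """Parameters of the growth model and its explicit solver.

    Material and growth values are dimensionless: lengths in units of the
    normalized half longitudinal length, moduli in units of mu_g.

    g_g, g_w : tangential area growth ratio at the cortical surface and in
        the innermost white matter (1 = no growth).
    mu_g, mu_w : shear moduli of gray and white matter (stiffness ratio
        mu_g/mu_w = 1 in the cross-species study conditions).
    bulk_ratio : K/mu (modest compressibility; 5 by default).
    h0, h_slope : normalized cortical thickness schedule h(t) = h0 - h_slope*t.
    protocol : "continuous" or "step-wise"; step-wise resets the stress-free
        reference to the current geometry at each entry of stage_times.
    g_increment : largest growth-ratio step applied between relaxations.
    dt : explicit pseudo-time step (None: 0.3, stable with the lumped
        stiffness masses used here).
    damping : optional extra viscous velocity decay per step (FIRE is
        self-damping; leave at 0 unless a run shows ringing).
    contact_range, contact_stiffness : self-contact penalty activation
        distance (None: 0.75 x mean boundary edge) and stiffness.
    force_tol : residual force infinity-norm for convergence.
    """

    g_g: float = 1.8
    g_w: float = 1.0
    mu_g: float = 1.0
    mu_w: float = 1.0
    bulk_ratio: float = 5.0
    h0: float = 0.1
    h_slope: float = 0.005
    protocol: str = "continuous"
    stage_times: tuple = ()
    t_end: float = 1.0
    g_increment: float = 0.02
    dt: float | None = None
    damping: float = 0.0
    contact_stiffness: float = 50.0
    contact_range: float | None = None
    contact_every: int = 25
    max_iters: int = 1500
    force_tol: float = 1e-4
    seed: int = 0
    growth_mask: np.ndarray | None = None  # per-vertex multiplier on (g - 1)

    def __post_init__(self):
        if self.g_g <= 0 or self.g_w <= 0:
            raise ValueError("growth ratios must be positive")
        if self.bulk_ratio <= 0:
            raise ValueError("bulk_ratio must be positive")
        if self.h0 <= 0 or self.h0 - self.h_slope * self.t_end <= 0:
            raise ValueError("cortical thickness must stay positive on [0, t_end]")
        if self.protocol not in ("continuous", "step-wise"):
            raise ValueError("protocol must be 'continuous' or 'step-wise'")

    def h_at(self, t: float) -> float:
        return self.h0 - self.h_slope * t


@dataclass
class SimState:
    """Reference + current configuration of the growing solid.

    Per-tet arrays: d (reference distance of the centroid to the cortical
    surface), n (unit growth-normal direction), mu, g.  Dm_inv and vol0
    cache the reference shape matrices; Ginv the inverse growth tensors.
    """

    reference_vertices: np.ndarray
    current_vertices: np.ndarray
    tets: np.ndarray
    d: np.ndarray
    n: np.ndarray
    mu: np.ndarray
    g: np.ndarray
    Dm_inv: np.ndarray
    vol0: np.ndarray
    Ginv: np.ndarray
    boundary_faces: np.ndarray
    t: float = 0.0
    total_energy: float = 0.0
    energy_trace: list = field(default_factory=list)
    contact_pairs: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=np.int64)
    )
    fixed: np.ndarray | None = None  # vertex indices pinned in place
    _contact_excluded: np.ndarray | None = None

    def deformation_gradients(self) -> np.ndarray:
        """F per tet, shape (T, 3, 3)."""
        x = self.current_vertices
        t = self.tets
        Ds = np.stack(
            [x[t[:, a]] - x[t[:, 0]] for a in (1, 2, 3)], axis=2
        )  # columns are edges
        return np.einsum("eij,ejk->eik", Ds, np.transpose(self.Dm_inv, (0, 2, 1)))

    def elastic_parts(self) -> np.ndarray:
        """A = F G^-1 per tet."""
        return np.einsum("eij,ejk->eik", self.deformation_gradients(), self.Ginv)

    def copy_shallow(self) -> "SimState":
        return replace(
            self,
            current_vertices=self.current_vertices.copy(),
            energy_trace=list(self.energy_trace),
        )


# ---------------------------------------------------------------- geometry


def _closest_point_on_triangles(p, a, b, c):
    """Closest point on each triangle (a, b, c) to each point p (paired
    arrays, all (N, 3)); Ericson's region decomposition, vectorized."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def fill(mask, val):
        m = mask & ~done
        out[m] = val[m]
        done[m] = True

    fill((d1 <= 0) & (d2 <= 0), a)  # vertex a
    fill((d3 >= 0) & (d4 <= d3), b)  # vertex b
    fill((d6 >= 0) & (d5 <= d6), c)  # vertex c
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3 + (d1 == d3)), 0.0)
    fill((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)  # edge ab
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6 + (d2 == d6)), 0.0)
    fill((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)  # edge ac
    va = d3 * d6 - d5 * d4
    denom_bc = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where(denom_bc != 0, (d4 - d3) / (denom_bc + (denom_bc == 0)), 0.0)
    fill((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w_bc[:, None] * (c - b))
    # interior
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    fill(np.ones(len(p), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)
    return out


def boundary_distance_field(volume: TetVolume):
    """Distance d and inward unit direction n to the boundary surface.

    d is the exact Euclidean distance from each vertex to the boundary
    triangle mesh in the reference configuration; n points from the
    nearest boundary point toward the vertex (the inward gradient of d).
    On boundary vertices, where the gradient degenerates, n is the inward
    vertex normal.
    """
    surf = volume.boundary_surface()
    return _distance_to_surface(volume.vertices, surf)


def _distance_to_surface(points: np.ndarray, surf: TriSurface):
    v = surf.vertices
    f = surf.faces
    # vertex -> incident faces, padded
    deg = np.zeros(len(v), dtype=np.int64)
    for c in range(3):
        np.add.at(deg, f[:, c], 1)
    maxdeg = max(int(deg.max()), 1)
    incident = -np.ones((len(v), maxdeg), dtype=np.int64)
    cursor = np.zeros(len(v), dtype=np.int64)
    for fi, tri in enumerate(f):
        for vi in tri:
            incident[vi, cursor[vi]] = fi
            cursor[vi] += 1

    used = np.unique(f)
    tree = cKDTree(v[used])
    k = min(6, len(used))
    d_out = np.empty(len(points))
    n_out = np.empty((len(points), 3))
    chunk = 8192
    for lo in range(0, len(points), chunk):
        p = points[lo : lo + chunk]
        _, nearest = tree.query(p, k=k)
        nearest = np.atleast_2d(nearest)
        cand = incident[used[nearest]].reshape(len(p), -1)  # (m, k*maxdeg)
        ncand = cand.shape[1]
        valid = cand >= 0
        cand_safe = np.where(valid, cand, 0)
        tri = f[cand_safe]  # (m, ncand, 3)
        pp = np.repeat(p, ncand, axis=0)
        cps = _closest_point_on_triangles(
            pp,
            v[tri[:, :, 0]].reshape(-1, 3),
            v[tri[:, :, 1]].reshape(-1, 3),
            v[tri[:, :, 2]].reshape(-1, 3),
        ).reshape(len(p), ncand, 3)
        dist = np.linalg.norm(cps - p[:, None, :], axis=2)
        dist = np.where(valid, dist, np.inf)
        best = np.argmin(dist, axis=1)
        rows = np.arange(len(p))
        d_out[lo : lo + chunk] = dist[rows, best]
        n_out[lo : lo + chunk] = p - cps[rows, best]

    norms = np.linalg.norm(n_out, axis=1)
    degenerate = norms < 1e-9
    if degenerate.any():
        # inward vertex normals for points sitting on the boundary
        fn = surf.face_normals() * surf.face_areas()[:, None]
        vn = np.zeros((len(v), 3))
        for c in range(3):
            np.add.at(vn, f[:, c], fn)
        _, nearest_v = tree.query(points[degenerate])
        inward = -vn[used[nearest_v]]
        n_out[degenerate] = inward
        norms = np.linalg.norm(n_out, axis=1)
    n_out /= np.maximum(norms, 1e-300)[:, None]
    return d_out, n_out


# ------------------------------------------------------------- primitives


def sigmoid_profile(d, h, val_surface, val_deep):
    """Sigmoid depth profile: val_deep + (val_surface - val_deep) /
    (1 + exp(10 (d/h - 1))).  Halfway exactly at d = h."""
    d = np.asarray(d, dtype=np.float64)
    if h <= 0:
        raise ValueError("thickness h must be positive")
    with np.errstate(over="ignore"):  # deep tail saturates to val_deep
        return val_deep + (val_surface - val_deep) / (
            1.0 + np.exp(10.0 * (d / h - 1.0))
        )


def growth_tensor(g: float, n) -> np.ndarray:
    """Tangential growth tensor sqrt(g) I + (1 - sqrt(g)) n (x) n.

    Eigenvalues (sqrt(g), sqrt(g), 1) with G n = n; det G = g.
    """
    n = np.asarray(n, dtype=np.float64)
    if abs(np.linalg.norm(n) - 1.0) > 1e-8:
        raise ValueError("n must be a unit vector")
    if g <= 0:
        raise ValueError("growth ratio must be positive")
    rg = np.sqrt(g)
    return rg * np.eye(3) + (1.0 - rg) * np.outer(n, n)


def _inverse_growth_tensors(g: np.ndarray, n: np.ndarray) -> np.ndarray:
    """G^-1 per tet: (1/sqrt(g)) (I - n n^T) + n n^T (symmetric)."""
    rg = np.sqrt(g)
    eye = np.eye(3)[None, :, :]
    nn = n[:, :, None] * n[:, None, :]
    return (eye - nn) / rg[:, None, None] + nn


def neo_hookean_energy(F, G, mu: float, K_bulk: float) -> float:
    """Strain-energy density W(A) with A = F G^-1 (single tensor pair)."""
    F = np.asarray(F, dtype=np.float64)
    G = np.asarray(G, dtype=np.float64)
    if np.linalg.det(F) <= 0 or np.linalg.det(G) <= 0:
        raise ValueError("det F and det G must be positive")
    A = F @ np.linalg.inv(G)
    J = np.linalg.det(A)
    if J <= 0:
        raise ValueError("det A must be positive")
    I1 = float(np.sum(A * A))
    return float(0.5 * mu * (J ** (-2.0 / 3.0) * I1 - 3.0) + 0.5 * K_bulk * (J - 1.0) ** 2)


# ------------------------------------------------------------- assembly


def init_state(volume: TetVolume, config: GrowthConfig, t: float = 0.0) -> SimState:
    """Stress-free state at the reference geometry with g = 1 everywhere."""
    verts = np.ascontiguousarray(volume.vertices)
    tets = np.ascontiguousarray(volume.tets)
    vol0 = volume.tet_volumes()
    if (vol0 <= 0).any():
        raise ValueError("input TetVolume has non-positive tets")
    # Dm columns are reference edge vectors; F = Ds Dm^-1
    Dm = np.stack([verts[tets[:, a]] - verts[tets[:, 0]] for a in (1, 2, 3)], axis=2)
    Dm_inv = np.linalg.inv(Dm)

    centroids = verts[tets].mean(axis=1)
    surf = TriSurface(verts, boundary_faces_of_tets(tets))
    d, n = _distance_to_surface(centroids, surf)
    n_tet = len(tets)
    g = np.ones(n_tet)
    mu = np.full(n_tet, config.mu_g)
    state = SimState(
        reference_vertices=verts.copy(),
        current_vertices=verts.copy(),
        tets=tets,
        d=d,
        n=n,
        mu=mu,
        g=g,
        Dm_inv=np.ascontiguousarray(Dm_inv),
        vol0=vol0,
        Ginv=_inverse_growth_tensors(g, n),
        boundary_faces=surf.faces,
        t=t,
    )
    state._contact_excluded = _contact_exclusion(state, config)
    return state


def _contact_rc(state: SimState, config: GrowthConfig) -> float:
    if config.contact_range is not None:
        return config.contact_range
    bf = state.boundary_faces
    v = state.reference_vertices
    e = np.linalg.norm(v[bf[:, 0]] - v[bf[:, 1]], axis=1)
    return 0.75 * float(e.mean())


def _contact_exclusion(state: SimState, config: GrowthConfig) -> np.ndarray:
    """Sorted keys i*N+j of boundary vertex pairs that are close along the
    reference surface (within a few rings) and therefore exempt from
    contact: material neighbors may legitimately sit within contact range."""
    rc = _contact_rc(state, config)
    r_excl = 2.5 * rc
    bf = state.boundary_faces
    v = state.reference_vertices
    edges = np.sort(bf[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    edges = np.unique(edges, axis=0)
    mean_edge = float(
        np.linalg.norm(v[edges[:, 0]] - v[edges[:, 1]], axis=1).mean()
    )
    hops = max(2, int(np.ceil(r_excl / max(mean_edge, 1e-12))) + 1)
    nv = len(v)
    ones = np.ones(len(edges), dtype=bool)
    adj = csr_matrix(
        (
            np.r_[ones, ones],
            (np.r_[edges[:, 0], edges[:, 1]], np.r_[edges[:, 1], edges[:, 0]]),
        ),
        shape=(nv, nv),
        dtype=bool,
    )
    from scipy.sparse import eye as speye

    reach = adj + speye(nv, dtype=bool, format="csr")
    base = reach
    for _ in range(hops - 1):
        reach = (reach @ base).astype(bool)
    reach = reach.tocoo()
    i, j = reach.row, reach.col
    sel = i < j
    keys = i[sel].astype(np.int64) * nv + j[sel]
    return np.sort(keys)


def _rebuild_contact_pairs(state: SimState, config: GrowthConfig) -> None:
    rc = _contact_rc(state, config)
    bverts = np.unique(state.boundary_faces)
    tree = cKDTree(state.current_vertices[bverts])
    pairs = tree.query_pairs(rc, output_type="ndarray")
    if len(pairs) == 0:
        state.contact_pairs = np.empty((0, 2), dtype=np.int64)
        return
    gi = bverts[pairs[:, 0]]
    gj = bverts[pairs[:, 1]]
    lo = np.minimum(gi, gj)
    hi = np.maximum(gi, gj)
    keys = lo * len(state.current_vertices) + hi
    keep = ~np.isin(keys, state._contact_excluded, assume_unique=False)
    state.contact_pairs = np.column_stack([lo[keep], hi[keep]]).astype(np.int64)


def total_energy_and_forces(state: SimState, config: GrowthConfig):
    """Total energy (elastic + contact penalty) and its exact negative
    gradient with respect to the current vertex positions."""
    x = state.current_vertices
    forces = np.zeros_like(x)
    kbulk = config.bulk_ratio * state.mu
    energy, min_detF = elastic_energy_forces(
        x, state.tets, state.Dm_inv, state.vol0, state.Ginv, state.mu, kbulk, forces
    )
    if min_detF <= 0:
        bad = _find_inverted(state)
        raise RuntimeError(f"inverted element(s) encountered: tets {bad[:10]}")
    rc = _contact_rc(state, config)
    if len(state.contact_pairs):
        energy += contact_energy_forces(
            x, state.contact_pairs, rc, config.contact_stiffness, forces
        )
    state.total_energy = float(energy)
    return float(energy), forces


def _find_inverted(state: SimState) -> list[int]:
    F = state.deformation_gradients()
    det = np.linalg.det(F)
    return list(np.where(det <= 0)[0])


def _stability_masses(state: SimState, config: GrowthConfig) -> np.ndarray:
    """Lumped pseudo-masses from element stiffness scales, so a unit
    pseudo-time step is stable for the explicit iteration."""
    stiff = np.einsum("eij,eij->e", state.Dm_inv, state.Dm_inv)
    k_e = state.vol0 * (state.mu * (1.0 + config.bulk_ratio)) * stiff
    m = np.zeros(len(state.current_vertices))
    np.add.at(m, state.tets.ravel(), np.repeat(k_e, 4))
    # boundary vertices also feel the contact penalty stiffness
    return np.maximum(m, 1e-12) + 0.05 * config.contact_stiffness


def relax(state: SimState, config: GrowthConfig) -> SimState:
    """Damped explicit quasi-static relaxation to a force-balanced state.

    FIRE (fast inertial relaxation engine) with per-vertex stiffness
    masses: the pseudo-time step grows while the motion descends (power
    f.v > 0) and velocities reset when it stops descending, which lets
    slow, soft modes — the folding instability — develop orders of
    magnitude faster than fixed-step damped dynamics.  A safeguard
    reverts to the best-energy state whenever the energy rises beyond
    tolerance, keeping the energy trace non-increasing across windows.
    Stops when the largest nodal force drops below force_tol or after
    max_iters.
    """
    x = state.current_vertices
    m = _stability_masses(state, config)[:, None]
    dt0 = config.dt if config.dt is not None else 0.3
    dt = dt0
    dt_max = 10.0 * dt0
    alpha0 = 0.15
    alpha = alpha0
    n_good = 0
    v = np.zeros_like(x)
    best_x = x.copy()
    best_E = np.inf
    bad_streak = 0
    _rebuild_contact_pairs(state, config)
    for it in range(config.max_iters):
        if it % config.contact_every == 0 and it > 0:
            _rebuild_contact_pairs(state, config)
        try:
            energy, f = total_energy_and_forces(state, config)
        except RuntimeError:
            # inverted element: back off to the best state seen
            x[:] = best_x
            v[:] = 0.0
            dt = max(0.25 * dt, 0.05 * dt0)
            dt_max = max(0.5 * dt_max, dt0)
            alpha = alpha0
            n_good = 0
            bad_streak += 1
            if bad_streak > 12:
                raise
            continue
        state.energy_trace.append(energy)
        if state.fixed is not None:
            f[state.fixed] = 0.0
        fmax = np.abs(f).max()
        if fmax < config.force_tol:
            if energy < best_E:
                best_E, best_x[:] = energy, x
            break
        if energy < best_E:
            best_E = energy
            best_x[:] = x
        elif energy > best_E * (1.0 + 1e-6) + 1e-300 and it % 50 == 49:
            # runaway ascent: restart from the best point, gentler step
            x[:] = best_x
            v[:] = 0.0
            dt = max(0.5 * dt, 0.05 * dt0)
            alpha = alpha0
            n_good = 0
            continue
        v += dt * f / m
        power = float(np.einsum("ij,ij->", f, v))
        if power > 0.0:
            vn = np.linalg.norm(v)
            fn = np.linalg.norm(f / m)
            if fn > 0:
                v = (1.0 - alpha) * v + alpha * (vn / fn) * (f / m)
            n_good += 1
            if n_good > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        else:
            v[:] = 0.0
            dt = max(dt * 0.5, 0.05 * dt0)
            alpha = alpha0
            n_good = 0
        if config.damping:
            v *= 1.0 - config.damping
        x += dt * v
    else:
        # out of iterations: keep the best state visited
        if best_E < np.inf:
            x[:] = best_x
    state.current_vertices = x
    total_energy_and_forces(state, config)  # refresh energy at the final point
    state.energy_trace.append(state.total_energy)
    return state


def _update_profiles(state: SimState, config: GrowthConfig, g_surf: float, g_deep: float, t: float):
    h = config.h_at(t)
    if h <= 0:
        raise ValueError(f"cortical thickness non-positive at t={t}")
    state.mu = sigmoid_profile(state.d, h, config.mu_g, config.mu_w)
    g = sigmoid_profile(state.d, h, g_surf, g_deep)
    if config.growth_mask is not None:
        mask_tet = config.growth_mask[state.tets].mean(axis=1)
        g = 1.0 + (g - 1.0) * mask_tet
    state.g = g
    state.Ginv = _inverse_growth_tensors(g, state.n)
    state.t = t


def _reset_reference(state: SimState, config: GrowthConfig) -> None:
    """Adopt the current geometry as the new stress-free reference
    (step-wise protocol): growth restarts from g = 1 and the stored
    elastic energy returns to zero by construction."""
    verts = state.current_vertices.copy()
    state.reference_vertices = verts
    Dm = np.stack(
        [verts[state.tets[:, a]] - verts[state.tets[:, 0]] for a in (1, 2, 3)], axis=2
    )
    state.Dm_inv = np.ascontiguousarray(np.linalg.inv(Dm))
    state.vol0 = TetVolume(verts, state.tets).tet_volumes()
    if (state.vol0 <= 0).any():
        raise RuntimeError("reference reset found inverted tets")
    centroids = verts[state.tets].mean(axis=1)
    surf = TriSurface(verts, state.boundary_faces)
    state.d, state.n = _distance_to_surface(centroids, surf)
    state.g = np.ones(len(state.tets))
    state.Ginv = _inverse_growth_tensors(state.g, state.n)
    state._contact_excluded = _contact_exclusion(state, config)


def run_growth(
    volume: TetVolume,
    config: GrowthConfig,
    snapshot_times=None,
    progress: bool = False,
) -> list[SimState]:
    """Run the growth protocol; returns snapshots (always includes t_end).

    Continuous: the surface growth ratio ramps linearly from 1 to g_g over
    [0, t_end], applied in increments of at most g_increment with
    relaxation after each.  Step-wise: [0, t_end] is split at stage_times;
    at each stage boundary the relaxed geometry becomes the new
    stress-free reference and the ramp restarts from 1 within the stage.
    """
    if config.protocol == "step-wise" and config.stage_times:
        bounds = [0.0, *sorted(config.stage_times), config.t_end]
    else:
        bounds = [0.0, config.t_end]
    snapshot_times = sorted(snapshot_times) if snapshot_times else []
    state = init_state(volume, config)
    snapshots: list[SimState] = []
    for s0, s1 in zip(bounds[:-1], bounds[1:]):
        if s0 > 0.0 and config.protocol == "step-wise":
            _reset_reference(state, config)
        n_inc = max(1, int(np.ceil(abs(config.g_g - 1.0) / config.g_increment)))
        for k in range(1, n_inc + 1):
            tau = k / n_inc
            t = s0 + tau * (s1 - s0)
            g_surf = 1.0 + (config.g_g - 1.0) * tau
            g_deep = 1.0 + (config.g_w - 1.0) * tau
            _update_profiles(state, config, g_surf, g_deep, t)
            relax(state, config)
            if progress:
                print(
                    f"t={t:.3f} g_surf={g_surf:.3f} E={state.total_energy:.5f} "
                    f"iters={len(state.energy_trace)}"
                )
            while snapshot_times and snapshot_times[0] <= t + 1e-12:
                snapshot_times.pop(0)
                snapshots.append(state.copy_shallow())
    if not snapshots or snapshots[-1].t < config.t_end - 1e-12:
        snapshots.append(state.copy_shallow())
    return snapshots


def extract_boundary_surface(state: SimState) -> TriSurface:
    """Boundary surface of the tet mesh at the current positions,
    outward-oriented, with vertices compacted."""
    faces = state.boundary_faces
    used = np.unique(faces)
    remap = -np.ones(len(state.current_vertices), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriSurface(state.current_vertices[used], remap[faces])
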