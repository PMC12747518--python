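"""Growth model exactness, solver contracts, and folding mechanics."""

import numpy as np
import pytest

from gyralkit.growth import (
    GrowthConfig,
    _inverse_growth_tensors,
    _rebuild_contact_pairs,
    _reset_reference,
    boundary_distance_field,
    extract_boundary_surface,
    growth_tensor,
    init_state,
    neo_hookean_energy,
    relax,
    run_growth,
    sigmoid_profile,
    total_energy_and_forces,
)
from gyralkit.io import validate_surface
from gyralkit.synth import make_slab
from gyralkit.types import TetVolume


class TestGrowthTensor:
    def test_identity_at_unit_growth(self):
        assert np.allclose(growth_tensor(1.0, [0, 0, 1]), np.eye(3))

    @pytest.mark.parametrize("g", [1.2, 1.8, 2.5])
    def test_determinant_equals_growth_ratio(self, g):
        rng = np.random.default_rng(int(g * 10))
        n = rng.standard_normal(3)
        n /= np.linalg.norm(n)
        G = growth_tensor(g, n)
        assert np.linalg.det(G) == pytest.approx(g, rel=1e-12)
        assert np.abs(G @ n - n).max() < 1e-12
        w = np.sort(np.linalg.eigvalsh(G))
        assert np.allclose(w, [1.0, np.sqrt(g), np.sqrt(g)])

    def test_non_unit_normal_rejected(self):
        with pytest.raises(ValueError):
            growth_tensor(1.5, [0, 0, 2.0])


class TestSigmoidProfile:
    def test_halfway_at_one_thickness(self):
        assert sigmoid_profile(0.1, 0.1, 3.0, 1.0) == pytest.approx(2.0, abs=1e-15)

    def test_surface_value(self):
        expected = 1.0 + (3.0 - 1.0) / (1.0 + np.exp(-10.0))
        assert sigmoid_profile(0.0, 0.1, 3.0, 1.0) == pytest.approx(expected, rel=1e-15)

    def test_monotone_decay(self):
        d = np.linspace(0, 1, 200)
        vals = sigmoid_profile(d, 0.1, 2.0, 1.0)
        # strictly decreasing through the transition, flat only in the
        # saturated double-precision tails
        assert (np.diff(vals) <= 0).all()
        trans = (d > 0.05) & (d < 0.3)
        assert (np.diff(vals[trans]) < 0).all()


class TestNeoHookeanEnergy:
    def test_zero_at_pure_growth(self):
        G = growth_tensor(1.8, [0, 0, 1])
        assert neo_hookean_energy(G, G, 1.0, 5.0) == pytest.approx(0.0, abs=1e-14)

    def test_isochoric_diagonal_stretch(self):
        lam = 1.7
        A = np.diag([lam, 1 / lam, 1.0])
        expected = (lam**2 + lam**-2 - 2.0) / 2.0  # J = 1, mu = 1
        assert neo_hookean_energy(A, np.eye(3), 1.0, 5.0) == pytest.approx(expected)

    def test_nonnegative_for_random_states(self):
        # AM-GM: J^(-2/3) tr(A^T A) >= 3 whenever det A > 0
        rng = np.random.default_rng(0)
        count = 0
        while count < 10_000:
            A = rng.standard_normal((3, 3))
            if np.linalg.det(A) <= 1e-3:
                continue
            count += 1
            assert neo_hookean_energy(A, np.eye(3), 1.0, 5.0) >= -1e-12

    def test_inverted_state_rejected(self):
        A = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            neo_hookean_energy(A, np.eye(3), 1.0, 5.0)


class TestBoundaryDistanceField:
    def test_boundary_vertices_have_zero_distance(self, unit_ball_volume):
        d, n = boundary_distance_field(unit_ball_volume)
        bverts = np.unique(unit_ball_volume.boundary_surface().faces)
        assert np.abs(d[bverts]).max() < 1e-12
        assert np.abs(np.linalg.norm(n, axis=1) - 1.0).max() < 1e-9

    def test_center_distance_matches_radius(self, unit_ball_volume):
        d, _ = boundary_distance_field(unit_ball_volume)
        surf = unit_ball_volume.boundary_surface()
        e = np.sort(surf.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        e = np.unique(e, axis=0)
        mean_edge = np.linalg.norm(
            surf.vertices[e[:, 0]] - surf.vertices[e[:, 1]], axis=1
        ).mean()
        center = np.argmin(np.linalg.norm(unit_ball_volume.vertices, axis=1))
        assert abs(d[center] - 1.0) < 2 * mean_edge

    def test_bounds(self, small_brain_volume):
        d, _ = boundary_distance_field(small_brain_volume)
        r_max = np.linalg.norm(small_brain_volume.vertices, axis=1).max()
        assert (d >= 0).all()
        assert d.max() <= r_max

    def test_inward_direction_on_ball(self, unit_ball_volume):
        d, n = boundary_distance_field(unit_ball_volume)
        v = unit_ball_volume.vertices
        r = np.linalg.norm(v, axis=1)
        interior = (d > 0.2) & (r > 0.3)  # the exact center has no direction
        # inward means toward the center for a ball
        cos = np.einsum("ij,ij->i", n[interior], -v[interior]) / r[interior]
        assert cos.min() > 0.9


class TestForcesAreExactGradients:
    def test_elastic_forces_match_finite_differences(self, random_tet_mesh):
        cfg = GrowthConfig(contact_range=0.2, contact_stiffness=10.0)
        st = init_state(random_tet_mesh, cfg)
        # non-trivial growth + perturbed current state
        st.g = np.linspace(1.05, 1.4, len(st.tets))
        st.Ginv = _inverse_growth_tensors(st.g, st.n)
        rng = np.random.default_rng(5)
        st.current_vertices = st.current_vertices + 0.002 * rng.standard_normal(
            st.current_vertices.shape
        )
        _rebuild_contact_pairs(st, cfg)
        _, f = total_energy_and_forces(st, cfg)
        eps = 1e-6
        x = st.current_vertices
        fd = np.zeros_like(f)
        for i in range(len(x)):
            for c in range(3):
                x[i, c] += eps
                ep, _ = total_energy_and_forces(st, cfg)
                x[i, c] -= 2 * eps
                em, _ = total_energy_and_forces(st, cfg)
                x[i, c] += eps
                fd[i, c] = -(ep - em) / (2 * eps)
        assert np.abs(f - fd).max() / np.abs(fd).max() < 1e-5

    def test_contact_forces_match_finite_differences(self):
        p1 = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        pts = np.vstack([p1, p1 + [2.1, 0, 0]])
        vol = TetVolume(pts, np.array([[0, 1, 2, 3], [4, 5, 6, 7]]))
        cfg = GrowthConfig(contact_range=1.5, contact_stiffness=3.0)
        st = init_state(vol, cfg)
        _rebuild_contact_pairs(st, cfg)
        assert len(st.contact_pairs) > 0
        E, f = total_energy_and_forces(st, cfg)
        assert E > 0  # penalty active across the gap
        eps = 1e-6
        x = st.current_vertices
        fd = np.zeros_like(f)
        for i in range(len(x)):
            for c in range(3):
                x[i, c] += eps
                ep, _ = total_energy_and_forces(st, cfg)
                x[i, c] -= 2 * eps
                em, _ = total_energy_and_forces(st, cfg)
                x[i, c] += eps
                fd[i, c] = -(ep - em) / (2 * eps)
        assert np.abs(f - fd).max() / np.abs(fd).max() < 1e-7

    def test_translation_invariance(self, random_tet_mesh):
        cfg = GrowthConfig()
        st = init_state(random_tet_mesh, cfg)
        st.g = np.full(len(st.tets), 1.3)
        st.Ginv = _inverse_growth_tensors(st.g, st.n)
        E1, f1 = total_energy_and_forces(st, cfg)
        st.current_vertices = st.current_vertices + 7.5
        E2, f2 = total_energy_and_forces(st, cfg)
        assert abs(E1 - E2) < 1e-12 + 1e-12 * abs(E1)
        assert np.abs(f1 - f2).max() < 1e-10
        # zero net force on the free body
        assert np.abs(f1.sum(axis=0)).max() < 1e-10

    def test_no_contact_outside_range(self, random_tet_mesh):
        cfg = GrowthConfig(contact_range=1e-6, contact_stiffness=10.0)
        st = init_state(random_tet_mesh, cfg)
        _rebuild_contact_pairs(st, cfg)
        E, _ = total_energy_and_forces(st, cfg)
        st.contact_pairs = np.empty((0, 2), dtype=np.int64)
        E0, _ = total_energy_and_forces(st, cfg)
        assert E == E0  # no penalty contribution

    def test_inverted_element_reported_with_index(self, random_tet_mesh):
        cfg = GrowthConfig()
        st = init_state(random_tet_mesh, cfg)
        # mirror a tet's apex through its base plane: guaranteed inversion
        st.current_vertices = st.current_vertices.copy()
        a, b, c, d = random_tet_mesh.tets[0]
        base = st.current_vertices[[a, b, c]].mean(axis=0)
        st.current_vertices[d] = 2 * base - st.current_vertices[d]
        with pytest.raises(RuntimeError, match="inverted"):
            total_energy_and_forces(st, cfg)


class TestRelaxation:
    def test_no_growth_is_a_fixed_point(self, small_brain_volume):
        cfg = GrowthConfig(force_tol=1e-8, max_iters=200)
        st = init_state(small_brain_volume, cfg)
        relax(st, cfg)
        disp = np.abs(st.current_vertices - st.reference_vertices).max()
        assert disp < 1e-6  # g = 1 everywhere: stress free, nothing moves

    def test_energy_non_increasing_across_windows(self, small_brain_volume):
        cfg = GrowthConfig(force_tol=1e-7, max_iters=600)
        st = init_state(small_brain_volume, cfg)
        rng = np.random.default_rng(2)
        st.current_vertices = st.current_vertices + 0.004 * rng.standard_normal(
            st.current_vertices.shape
        )
        relax(st, cfg)
        trace = np.asarray(st.energy_trace)
        assert trace[-1] < trace[0]
        window = 100
        for lo in range(0, len(trace) - window, window):
            a, b = trace[lo], trace[lo + window]
            assert b <= a * (1 + 1e-6) + 1e-12
        # relaxed energy below the perturbed energy, no inverted tets
        F = st.deformation_gradients()
        assert np.linalg.det(F).min() > 0

    def test_relaxed_energy_not_above_input(self, small_brain_volume):
        cfg = GrowthConfig(force_tol=1e-7, max_iters=300)
        st = init_state(small_brain_volume, cfg)
        rng = np.random.default_rng(3)
        st.current_vertices = st.current_vertices + 0.003 * rng.standard_normal(
            st.current_vertices.shape
        )
        E0, _ = total_energy_and_forces(st, cfg)
        relax(st, cfg)
        assert st.total_energy <= E0


class TestRunGrowth:
    def test_no_growth_returns_input_geometry(self, small_brain_volume):
        cfg = GrowthConfig(
            g_g=1.0, g_w=1.0, force_tol=1e-8, max_iters=100, g_increment=0.5
        )
        snaps = run_growth(small_brain_volume, cfg)
        disp = np.abs(
            snaps[-1].current_vertices - small_brain_volume.vertices
        ).max()
        assert disp < 1e-6

    def test_stepwise_reset_zeroes_energy(self, small_brain_volume):
        cfg = GrowthConfig(
            g_g=1.2, protocol="step-wise", stage_times=(0.5,),
            g_increment=0.1, max_iters=150, force_tol=1e-5,
        )
        st = init_state(small_brain_volume, cfg)
        rng = np.random.default_rng(1)
        st.current_vertices = st.current_vertices + 0.01 * rng.standard_normal(
            st.current_vertices.shape
        )
        _reset_reference(st, cfg)
        E, _ = total_energy_and_forces(st, cfg)
        assert E == pytest.approx(0.0, abs=1e-12)

    def test_growth_invariants_maintained(self, small_brain_volume):
        cfg = GrowthConfig(g_g=1.3, g_increment=0.15, max_iters=250, force_tol=1e-5)
        snaps = run_growth(small_brain_volume, cfg)
        st = snaps[-1]
        # det G = g and G n = n on every tet
        rg = np.sqrt(st.g)
        G = rg[:, None, None] * np.eye(3) + (1 - rg)[:, None, None] * (
            st.n[:, :, None] * st.n[:, None, :]
        )
        assert np.abs(np.linalg.det(G) - st.g).max() < 1e-10
        assert np.abs(np.einsum("eij,ej->ei", G, st.n) - st.n).max() < 1e-10
        assert np.linalg.det(st.deformation_gradients()).min() > 0

    def test_surface_area_grows(self, small_brain_volume):
        cfg = GrowthConfig(g_g=1.4, g_increment=0.1, max_iters=300, force_tol=1e-5)
        snaps = run_growth(small_brain_volume, cfg)
        a0 = small_brain_volume.boundary_surface().area()
        a1 = extract_boundary_surface(snaps[-1]).area()
        assert a1 > a0

    def test_thickness_schedule_guard(self):
        with pytest.raises(ValueError):
            GrowthConfig(h0=0.05, h_slope=0.06, t_end=1.0)

    def test_growth_mask_suppresses_expansion(self, small_brain_volume):
        # a zero mask everywhere reduces the run to the no-growth case
        mask = np.zeros(small_brain_volume.n_vertices)
        cfg = GrowthConfig(
            g_g=1.4, g_increment=0.2, max_iters=200, force_tol=1e-7,
            growth_mask=mask,
        )
        snaps = run_growth(small_brain_volume, cfg)
        disp = np.abs(
            snaps[-1].current_vertices - small_brain_volume.vertices
        ).max()
        assert disp < 1e-6
        assert np.abs(snaps[-1].g - 1.0).max() < 1e-12


class TestExtractBoundarySurface:
    def test_closed_genus_zero_and_area(self, small_brain_volume):
        cfg = GrowthConfig()
        st = init_state(small_brain_volume, cfg)
        surf = extract_boundary_surface(st)
        rep = validate_surface(surf)
        assert rep.euler_characteristic == 2
        assert rep.genus_if_closed == 0
        # independent area recount
        v, f = surf.vertices, surf.faces
        areas = 0.5 * np.linalg.norm(
            np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]]), axis=1
        )
        assert surf.area() == pytest.approx(areas.sum())

    def test_outward_orientation_positive_volume(self, small_brain_volume):
        cfg = GrowthConfig()
        st = init_state(small_brain_volume, cfg)
        surf = extract_boundary_surface(st)
        v, f = surf.vertices, surf.faces
        vol6 = np.einsum(
            "ij,ij->i", np.cross(v[f[:, 0]], v[f[:, 1]]), v[f[:, 2]]
        ).sum()
        assert vol6 > 0


def _grown_slab(g_target, h, seed=0, shape=(48, 4, 10), extent=(2.0, 0.16, 0.4),
                max_iters=1500, n_inc=None):
    """Bilayer slab with a tangentially growing top layer; bottom clamped."""
    vol = make_slab(shape, extent, z_grade=1.4)
    cfg = GrowthConfig(
        g_g=g_target, h0=h, h_slope=0.0, force_tol=1e-6, max_iters=max_iters
    )
    st = init_state(vol, cfg)
    lz = extent[2]
    cz = st.reference_vertices[st.tets].mean(axis=1)[:, 2]
    st.d = lz - cz
    st.n = np.tile(np.array([0.0, 0.0, 1.0]), (len(st.tets), 1))
    ref = st.reference_vertices
    st.fixed = np.where(ref[:, 2] < 1e-9)[0]
    rng = np.random.default_rng(seed)
    bump = np.zeros(len(ref))
    for m in range(1, 25):
        bump += rng.standard_normal() / np.sqrt(m) * np.cos(
            np.pi * m * ref[:, 0] / extent[0] + rng.uniform(0, 2 * np.pi)
        )
    st.current_vertices = st.current_vertices.copy()
    st.current_vertices[:, 2] += 1e-3 * bump * (ref[:, 2] / lz)
    st.current_vertices[st.fixed] = ref[st.fixed]
    if n_inc is None:
        n_inc = max(1, int(np.ceil((g_target - 1) / 0.1)))
    for k in range(1, n_inc + 1):
        gs = 1 + (g_target - 1) * k / n_inc
        st.g = sigmoid_profile(st.d, h, gs, 1.0)
        st.Ginv = _inverse_growth_tensors(st.g, st.n)
        relax(st, cfg)
    mid = np.where((ref[:, 2] > lz - 1e-9) & (ref[:, 1] < 1e-9))[0]
    order = np.argsort(ref[mid, 0])
    prof = st.current_vertices[mid][order]
    x, z = prof[:, 0], prof[:, 2]
    core = (x > x.min() + 0.25) & (x < x.max() - 0.25)
    return z[core] - np.median(z[core])


class TestSlabFolding:
    """Creasing of an equal-modulus bilayer: below the sulcification
    threshold the surface stays flat; well above, deep folds appear."""

    def test_deflection_contrast_across_threshold(self):
        h = 0.1
        below = _grown_slab(1.5, h)
        above = _grown_slab(3.0, h)
        assert np.abs(below).max() < 0.1 * h
        assert np.abs(above).max() > 0.5 * h
        assert np.abs(above).max() > 10 * np.abs(below).max()
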