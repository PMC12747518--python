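"""Disk parameterization and quasi-conformal machinery."""

import copy

import numpy as np
import pytest

from gyralkit.diskmap import (
    _flipped_count,
    _ordered_boundary_loop,
    beltrami_coefficient,
    disk_conformal,
    landmark_qc_map,
    linear_beltrami_solve,
    pullback_field,
    surface_beltrami,
)
from gyralkit.types import ScalarField, TriSurface


@pytest.fixture(scope="module")
def disk_param(hemisphere):
    return disk_conformal(hemisphere)


class TestDiskConformal:
    def test_boundary_on_unit_circle(self, disk_param):
        r = np.linalg.norm(disk_param.uv[disk_param.boundary_loop], axis=1)
        assert np.abs(r - 1.0).max() < 1e-6

    def test_no_flipped_parameter_triangles(self, disk_param):
        assert _flipped_count(disk_param.uv, disk_param.faces) == 0

    def test_near_conformal_on_smooth_hemisphere(self, disk_param):
        assert disk_param.mean_abs_beltrami < 0.1

    def test_planar_disk_maps_to_itself_up_to_rotation(self, disk_param, hemisphere):
        # a flat mesh that already fills the unit disk
        flat = TriSurface(
            np.column_stack([disk_param.uv, np.zeros(len(disk_param.uv))]),
            hemisphere.faces.copy(),
        )
        D2 = disk_conformal(flat)
        z1 = disk_param.uv[:, 0] + 1j * disk_param.uv[:, 1]
        z2 = D2.uv[:, 0] + 1j * D2.uv[:, 1]
        # radii preserved, and the angular offset is a single rotation
        assert np.abs(np.abs(z2) - np.abs(z1)).max() < 1e-3
        inner = np.abs(z1) > 0.2
        rot = np.angle(z2[inner] / z1[inner])
        assert np.ptp(rot) < 1e-3

    def test_non_disk_input_rejected(self, icosphere4):
        with pytest.raises(ValueError):
            disk_conformal(icosphere4)

    def test_roundtrip_through_lbs(self, disk_param, hemisphere):
        # reconstruct the parameterization from its own Beltrami field
        mu = surface_beltrami(hemisphere, disk_param.uv)
        # solve on the flattened domain: use the uv itself as domain with
        # the map's residual coefficient, boundary pinned
        mu2 = beltrami_coefficient(disk_param.uv, disk_param.uv, disk_param.faces)
        out = linear_beltrami_solve(
            disk_param.uv,
            disk_param.faces,
            mu2,
            disk_param.boundary_loop,
            disk_param.uv[disk_param.boundary_loop],
        )
        assert np.abs(out - disk_param.uv).max() < 1e-6


class TestBeltramiCoefficient:
    def test_identity_map_zero(self, disk_param):
        mu = beltrami_coefficient(disk_param.uv, disk_param.uv, disk_param.faces)
        assert np.abs(mu).max() < 1e-12

    def test_antiholomorphic_half(self, disk_param):
        z = disk_param.uv[:, 0] + 1j * disk_param.uv[:, 1]
        w = z + 0.5 * np.conj(z)
        mu = beltrami_coefficient(
            disk_param.uv, np.column_stack([w.real, w.imag]), disk_param.faces
        )
        assert np.abs(mu - 0.5).max() < 1e-12

    def test_similarity_is_conformal(self, disk_param):
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        mu = beltrami_coefficient(
            disk_param.uv, 2.0 * disk_param.uv @ R.T, disk_param.faces
        )
        assert np.abs(mu).max() < 1e-12

    def test_orientation_reversal_exceeds_one(self, disk_param):
        flipped = disk_param.uv * [1.0, -1.0]
        mu = beltrami_coefficient(disk_param.uv, flipped, disk_param.faces)
        assert (np.abs(mu) > 1 - 1e-12).all()


class TestLinearBeltramiSolve:
    def test_zero_mu_with_identity_boundary(self, disk_param):
        out = linear_beltrami_solve(
            disk_param.uv,
            disk_param.faces,
            np.zeros(len(disk_param.faces), dtype=complex),
            disk_param.boundary_loop,
            disk_param.uv[disk_param.boundary_loop],
        )
        assert np.abs(out - disk_param.uv).max() < 1e-8

    def test_affine_recovery_from_two_points(self, disk_param):
        A = np.array([[1.2, 0.3], [0.1, 0.9]])
        tgt = disk_param.uv @ A.T + [0.05, -0.02]
        mu = beltrami_coefficient(disk_param.uv, tgt, disk_param.faces)
        assert np.abs(mu - mu[0]).max() < 1e-12  # constant for affine maps
        out = linear_beltrami_solve(
            disk_param.uv, disk_param.faces, mu, np.array([0, 50]), tgt[[0, 50]]
        )
        assert np.abs(out - tgt).max() < 1e-8

    def test_no_flips_for_moderate_mu(self, disk_param):
        rng = np.random.default_rng(42)
        cent = disk_param.uv[disk_param.faces].mean(axis=1)
        z = cent[:, 0] + 1j * cent[:, 1]
        flips = 0
        for _ in range(100):
            # smooth random coefficient: low-order polynomial in z, z~
            coef = rng.standard_normal(6) + 1j * rng.standard_normal(6)
            mu = (
                coef[0]
                + coef[1] * z
                + coef[2] * np.conj(z)
                + coef[3] * z**2
                + coef[4] * np.abs(z) ** 2
                + coef[5] * np.conj(z) ** 2
            )
            mu *= 0.9 * rng.random() / max(np.abs(mu).max(), 1e-12)
            out = linear_beltrami_solve(
                disk_param.uv,
                disk_param.faces,
                mu,
                disk_param.boundary_loop,
                disk_param.uv[disk_param.boundary_loop],
            )
            flips += _flipped_count(out, disk_param.faces) > 0
        assert flips == 0

    def test_excessive_mu_rejected(self, disk_param):
        mu = np.full(len(disk_param.faces), 1.2 + 0j)
        with pytest.raises(ValueError):
            linear_beltrami_solve(
                disk_param.uv,
                disk_param.faces,
                mu,
                disk_param.boundary_loop,
                disk_param.uv[disk_param.boundary_loop],
            )


class TestLandmarkQCMap:
    def test_identity_when_landmarks_agree(self, disk_param, hemi_landmarks):
        qc = landmark_qc_map(disk_param, disk_param, hemi_landmarks, hemi_landmarks)
        assert qc.landmark_residual < 1e-3
        assert np.abs(qc.image - disk_param.uv).max() < 1e-6
        assert qc.beltrami_abs.max() < 1.0

    def test_translated_landmarks_matched(self, disk_param, hemi_landmarks):
        D2 = copy.deepcopy(disk_param)
        D2.uv = D2.uv.copy()
        for c in hemi_landmarks:
            D2.uv[c.vertex_path] = disk_param.uv[c.vertex_path] + [0.03, 0.02]
        qc = landmark_qc_map(disk_param, D2, hemi_landmarks, hemi_landmarks, tol=1e-3)
        assert qc.landmark_residual < 1e-3
        assert qc.beltrami_abs.max() < 1.0
        assert _flipped_count(qc.image, disk_param.faces) == 0

    def test_inverse_roundtrip(self, disk_param, hemi_landmarks):
        from gyralkit.diskmap import DiskParam

        D2 = copy.deepcopy(disk_param)
        D2.uv = D2.uv.copy()
        for c in hemi_landmarks:
            D2.uv[c.vertex_path] = disk_param.uv[c.vertex_path] + [0.03, 0.02]
        tol = 1e-3
        fwd = landmark_qc_map(disk_param, D2, hemi_landmarks, hemi_landmarks, tol=tol)
        # invert the PL map itself: interpolate domain coordinates over the
        # image triangulation, evaluate at the domain vertex positions, and
        # push the result forward again
        image_disk = DiskParam(
            uv=fwd.image, faces=disk_param.faces, boundary_loop=disk_param.boundary_loop
        )
        inv_u = pullback_field(ScalarField(disk_param.uv[:, 0]), disk_param.uv, image_disk)
        inv_v = pullback_field(ScalarField(disk_param.uv[:, 1]), disk_param.uv, image_disk)
        q = np.column_stack([inv_u.values, inv_v.values])  # f^-1 at D1 vertices
        fwd_u = pullback_field(ScalarField(fwd.image[:, 0]), q, disk_param)
        fwd_v = pullback_field(ScalarField(fwd.image[:, 1]), q, disk_param)
        roundtrip = np.column_stack([fwd_u.values, fwd_v.values])
        interior = np.linalg.norm(disk_param.uv, axis=1) < 0.9
        err = np.linalg.norm((roundtrip - disk_param.uv)[interior], axis=1)
        assert np.median(err) < 10 * tol

    def test_mismatched_counts_rejected(self, disk_param, hemi_landmarks):
        with pytest.raises(ValueError):
            landmark_qc_map(
                disk_param, disk_param, hemi_landmarks, hemi_landmarks[:-1]
            )

    def test_monotone_correspondence_along_curves(self, disk_param, hemi_landmarks):
        D2 = copy.deepcopy(disk_param)
        D2.uv = D2.uv.copy()
        for c in hemi_landmarks:
            D2.uv[c.vertex_path] = disk_param.uv[c.vertex_path] + [0.02, -0.03]
        qc = landmark_qc_map(disk_param, D2, hemi_landmarks, hemi_landmarks)
        for c in hemi_landmarks:
            mapped = qc.image[c.vertex_path]
            seg = np.linalg.norm(np.diff(mapped, axis=0), axis=1)
            s = np.r_[0.0, np.cumsum(seg)]
            assert (np.diff(s) >= 0).all()


class TestPullbackField:
    def test_identity_chain_returns_field(self, disk_param):
        rng = np.random.default_rng(0)
        f = ScalarField(rng.uniform(-1, 1, disk_param.n_vertices))
        out = pullback_field(f, disk_param.uv, disk_param)
        assert np.abs(out.values - f.values).max() < 1e-12

    def test_constant_field_stays_constant(self, disk_param):
        f = ScalarField(np.full(disk_param.n_vertices, 0.42))
        rng = np.random.default_rng(1)
        pts = disk_param.uv * 0.8 + 0.01 * rng.standard_normal(disk_param.uv.shape)
        out = pullback_field(f, pts, disk_param)
        assert np.abs(out.values - 0.42).max() < 1e-12

    def test_linear_field_exact_under_affine_map(self, disk_param):
        # barycentric interpolation reproduces linear fields exactly
        a, b, c = 0.3, -0.7, 0.1
        f = ScalarField(a * disk_param.uv[:, 0] + b * disk_param.uv[:, 1] + c)
        A = np.array([[0.9, 0.1], [-0.05, 0.8]])
        pts = disk_param.uv @ A.T  # stays inside the disk
        out = pullback_field(f, pts, disk_param)
        expected = a * pts[:, 0] + b * pts[:, 1] + c
        assert np.abs(out.values - expected).max() < 1e-10

    def test_spilled_points_projected_to_boundary(self, disk_param):
        f = ScalarField(np.linspace(-1, 1, disk_param.n_vertices))
        pts = disk_param.uv * 1.05  # all pushed outside
        out = pullback_field(f, pts, disk_param)
        assert np.isfinite(out.values).all()


class TestBoundaryLoop:
    def test_loop_covers_all_boundary_vertices_once(self, hemisphere):
        loop = _ordered_boundary_loop(hemisphere)
        assert len(loop) == len(set(loop.tolist()))
        assert set(loop.tolist()) == set(hemisphere.boundary_vertices().tolist())
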