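"""Patch orientation, cone geometry and the EM/SEM/CEM/shape projections."""

import numpy as np
import pytest

from epizern.patch_projection import (
    ConeOrigin,
    DegeneratePatchError,
    ProjectionMatrix,
    cone_origin,
    em_to_cem,
    em_to_sem,
    fill_masked_pixels,
    fit_plane,
    orient_pair,
    orient_single,
    project_potential,
    project_shape,
)


def disk_points(radius=9.0, spacing=0.45, z=0.0, seed=0):
    rng = np.random.default_rng(seed)
    ax = np.arange(-radius, radius + spacing / 2, spacing)
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    xy = np.column_stack([X.ravel(), Y.ravel()])
    xy += rng.uniform(-0.2 * spacing, 0.2 * spacing, xy.shape)
    keep = np.hypot(xy[:, 0], xy[:, 1]) <= radius
    pts = np.column_stack([xy[keep], np.full(keep.sum(), z)])
    normals = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
    return pts, normals


class TestFitPlane:
    def test_exact_horizontal(self):
        pts, _ = disk_points()
        n, off = fit_plane(pts, reference_normal=[0, 0, 1])
        assert np.allclose(n, [0, 0, 1], atol=1e-9)
        assert abs(off) < 1e-9

    def test_exact_tilted_plane(self):
        pts, _ = disk_points()
        truth = np.array([1.0, 2.0, 4.0])
        truth /= np.linalg.norm(truth)
        R = np.linalg.svd(np.outer(truth, [0, 0, 1]) + np.eye(3) * 1e-3)[0]
        tilted = pts @ R.T
        n, _ = fit_plane(tilted, reference_normal=R @ [0, 0, 1])
        assert np.allclose(np.abs(n @ (R @ [0, 0, 1])), 1.0, atol=1e-9)

    def test_noisy_plane_within_two_degrees(self):
        pts, _ = disk_points()
        rng = np.random.default_rng(1)
        noisy = pts + np.column_stack(
            [np.zeros((len(pts), 2)), rng.normal(0, 0.1, len(pts))]
        )
        n, _ = fit_plane(noisy, reference_normal=[0, 0, 1])
        angle = np.degrees(np.arccos(np.clip(n[2], -1, 1)))
        assert angle < 2.0

    def test_collinear_error(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(DegeneratePatchError):
            fit_plane(pts)


class TestOrientSingle:
    def test_flat_up_is_identity_like(self):
        pts, nrm = disk_points()
        op = orient_single(pts, nrm, direction="up")
        assert np.allclose(op.rotation, np.eye(3), atol=1e-6)
        assert np.allclose(op.points.mean(axis=0), 0.0, atol=1e-9)

    def test_down_negates_z_exactly(self):
        pts, nrm = disk_points()
        pts = pts + np.column_stack(
            [np.zeros((len(pts), 2)), 0.05 * pts[:, 0] ** 2]
        )
        up = orient_single(pts, nrm, direction="up")
        down = orient_single(pts, nrm, direction="down")
        assert np.allclose(down.points, up.points * [1, 1, -1], atol=1e-12)

    def test_near_planar_patch_mean_normal_along_z(self):
        # paraboloid cap
        pts, _ = disk_points(radius=6.0)
        z = (pts[:, 0] ** 2 + 2 * pts[:, 1] ** 2) / 40.0
        pts = np.column_stack([pts[:, :2], z])
        nrm = np.column_stack(
            [-pts[:, 0] / 20.0, -pts[:, 1] / 10.0, np.ones(len(pts))]
        )
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        op = orient_single(pts, nrm, direction="up")
        mean_n = op.normals.mean(axis=0)
        assert abs(mean_n[2] / np.linalg.norm(mean_n)) >= 0.99


class TestOrientPair:
    def test_already_facing_identity(self):
        pts_a, nrm_a = disk_points(z=0.0)
        pts_b, nrm_b = disk_points(z=2.0, seed=1)
        opA, opB = orient_pair(pts_a, nrm_a, pts_b, -nrm_b)
        assert np.allclose(opA.rotation, np.eye(3), atol=1e-6)
        assert opA.orientation == "up" and opB.orientation == "down"

    def test_rigid_rotation_preserves_pixel_correspondence(self, default_complex, default_patches):
        from scipy.spatial.transform import Rotation

        psurf_A, psurf_B, _ = default_complex
        patch_A, patch_B = default_patches
        iA, iB = patch_A.point_indices, patch_B.point_indices

        def f_of(ptsA, nrmA, ptsB, nrmB):
            from epizern.scoring import f_score

            opA, opB = orient_pair(
                ptsA, nrmA, ptsB, nrmB,
                values_A=psurf_A.potential[iA], values_B=psurf_B.potential[iB],
            )
            scale = max(
                np.hypot(opA.points[:, 0], opA.points[:, 1]).max(),
                np.hypot(opB.points[:, 0], opB.points[:, 1]).max(),
            )
            semA = em_to_sem(project_potential(opA, disk_scale=scale))
            semB = em_to_sem(project_potential(opB, disk_scale=scale))
            return f_score(semA, semB).value

        base = f_of(
            psurf_A.surface.points[iA], psurf_A.surface.normals[iA],
            psurf_B.surface.points[iB], psurf_B.surface.normals[iB],
        )
        R = Rotation.random(rng=np.random.default_rng(7)).as_matrix()
        rotated = f_of(
            psurf_A.surface.points[iA] @ R.T, psurf_A.surface.normals[iA] @ R.T,
            psurf_B.surface.points[iB] @ R.T, psurf_B.surface.normals[iB] @ R.T,
        )
        assert abs(base - rotated) < 0.02

    def test_facing_flat_patches_project_congruently(self):
        pts_a, nrm_a = disk_points(z=0.0, seed=2)
        pts_b = pts_a + [0.0, 0.0, 2.0]  # exactly facing points
        opA, opB = orient_pair(pts_a, nrm_a, pts_b, -nrm_a)
        assert np.allclose(opA.points[:, :2], opB.points[:, :2], atol=1e-9)

    def test_degenerate_normals_error(self):
        pts, nrm = disk_points()
        with pytest.raises(DegeneratePatchError):
            orient_pair(pts, nrm, pts, nrm)  # mean normals cancel in v = nA - nB


class TestConeOrigin:
    def test_flat_disk_radius_nine(self):
        pts, nrm = disk_points(radius=9.0)
        op = orient_single(pts, nrm, direction="up")
        cone = cone_origin(op)
        rho_max = np.hypot(op.points[:, 0], op.points[:, 1]).max()
        assert cone.C[2] == pytest.approx(rho_max, rel=1e-4)

    def test_flat_disk_half_radius(self):
        pts, nrm = disk_points(radius=4.5)
        op = orient_single(pts, nrm, direction="up")
        cone = cone_origin(op)
        rho_max = np.hypot(op.points[:, 0], op.points[:, 1]).max()
        assert cone.C[2] == pytest.approx(rho_max, rel=1e-4)

    def test_scaling_similarity(self):
        pts, nrm = disk_points(radius=6.0)
        z = (pts[:, 0] ** 2 + pts[:, 1] ** 2) / 30.0
        pts = np.column_stack([pts[:, :2], z])
        op = orient_single(pts, nrm, direction="up")
        h1 = cone_origin(op).C[2]
        op2 = orient_single(pts * 2.0, nrm, direction="up")
        h2 = cone_origin(op2).C[2]
        assert h2 == pytest.approx(2.0 * h1, rel=1e-3)


class TestProjections:
    def test_flat_disk_shape_matrix_geometry(self):
        pts, nrm = disk_points(radius=9.0, spacing=0.3)
        op = orient_single(pts, nrm, direction="up")
        cone = cone_origin(op)
        h = cone.C[2]
        m = project_shape(op, cone)
        center = m.grid[12, 12]
        assert center == pytest.approx(h, rel=0.02)
        # r = sqrt(h^2 + rho^2) at the disk rim
        rim_val = m.grid[12, m.mask[12].nonzero()[0].max()]
        assert rim_val == pytest.approx(np.hypot(h, m.disk_scale), rel=0.05)

    def test_concave_spherical_cap_constant_distance(self):
        # dent cap: all points on a sphere of radius R centred above the
        # patch; the 45-degree cone apex coincides with the sphere centre
        R = 10.0
        rng = np.random.default_rng(3)
        rho = R * np.sqrt(rng.uniform(0, np.sin(np.pi / 4) ** 2, 4000))
        phi = rng.uniform(0, 2 * np.pi, 4000)
        x, y = rho * np.cos(phi), rho * np.sin(phi)
        z = -np.sqrt(R**2 - rho**2)
        pts = np.column_stack([x, y, z])
        nrm = -pts / np.linalg.norm(pts, axis=1, keepdims=True)  # toward centre
        op = orient_single(pts, nrm, direction="up")
        cone = cone_origin(op)
        m = project_shape(op, cone)
        vals = m.grid[m.mask]
        assert np.allclose(vals, R, rtol=0.02)

    def test_empty_pixels_masked(self):
        pts, nrm = disk_points(radius=9.0, spacing=2.0)
        op = orient_single(pts, nrm, direction="up")
        m = project_shape(op, cone_origin(op))
        assert not m.mask.all()
        assert np.all(m.grid[~m.mask] == 0.0)

    def test_uniform_potential(self):
        pts, nrm = disk_points()
        op = orient_single(pts, nrm, values=np.full(len(pts), 7.0), direction="up")
        m = project_potential(op)
        assert np.allclose(m.grid[m.mask], 7.0)

    def test_pixel_mean_of_two_points(self):
        pts = np.array([[0.0, 0.0, 0.0], [0.05, 0.05, 0.0], [5.0, 0, 0], [0, 5, 0], [-5, 0, 0], [0, -5, 0], [3, 3, 0]])
        nrm = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
        op = orient_single(pts, nrm, values=np.array([2.0, 4.0, 0, 0, 0, 0, 0]), direction="up")
        m = project_potential(op, n_pixels=5)
        # the two nearby points share the central pixel
        centre_pix = m.grid[2, 2]
        assert centre_pix == pytest.approx(3.0)

    def test_linear_field_reproduces_pixel_centres(self):
        pts, nrm = disk_points(radius=9.0, spacing=0.15)
        op = orient_single(pts, nrm, values=pts[:, 0].copy(), direction="up")
        m = project_potential(op)
        c = (np.arange(25) + 0.5) * m.pixel_size - m.disk_scale
        for i in (5, 12, 20):
            row = m.grid[i, m.mask[i]]
            assert np.all(np.abs(row.mean() - c[i]) <= m.pixel_size / 2 + 1e-9)

    def test_em_negation_antisymmetry(self, default_complex, default_patches):
        psurf_A, _, _ = default_complex
        patch_A, _ = default_patches
        i = patch_A.point_indices
        pts, nrm = psurf_A.surface.points[i], psurf_A.surface.normals[i]
        op_pos = orient_single(pts, nrm, values=psurf_A.potential[i], direction="up")
        op_neg = orient_single(pts, nrm, values=-psurf_A.potential[i], direction="up")
        m_pos, m_neg = project_potential(op_pos), project_potential(op_neg)
        assert np.allclose(m_pos.grid, -m_neg.grid)
        assert np.array_equal(m_pos.mask, m_neg.mask)


class TestSemCem:
    def _em(self, grid, mask=None):
        grid = np.asarray(grid, dtype=float)
        mask = np.ones_like(grid, dtype=bool) if mask is None else mask
        return ProjectionMatrix("EM", grid, mask, 0.1, 1.0)

    def test_sem_signs_and_zero_masking(self):
        em = self._em([[12.3, -4.5], [0.0, 2.0]])
        sem = em_to_sem(em)
        assert sem.grid[0, 0] == 1.0 and sem.grid[0, 1] == -1.0
        assert not sem.mask[1, 0]  # exact zero masked out
        assert sem.grid[1, 1] == 1.0

    def test_cem_capping(self):
        em = self._em([[45.0, -100.0], [12.0, 0.0]])
        cem = em_to_cem(em, cap=30.0)
        assert cem.grid[0, 0] == 30.0
        assert cem.grid[0, 1] == -30.0
        assert cem.grid[1, 0] == 12.0

    def test_cem_idempotent(self):
        em = self._em(np.random.default_rng(0).normal(0, 50, (25, 25)))
        once = em_to_cem(em)
        twice = em_to_cem(once)
        assert np.array_equal(once.grid, twice.grid)

    def test_fill_masked_pixels(self):
        rng = np.random.default_rng(1)
        grid = rng.normal(10, 1, (25, 25))
        mask = rng.random((25, 25)) > 0.1
        em = ProjectionMatrix("SHAPE", np.where(mask, grid, 0.0), mask, 0.1, 1.0)
        filled = fill_masked_pixels(em)
        c = (np.arange(25) + 0.5) * (2 / 25) - 1
        X, Y = np.meshgrid(c, c, indexing="ij")
        in_disk = np.hypot(X, Y) <= 1.0
        assert filled.mask[in_disk].all()
        # original masked-in values untouched
        assert np.array_equal(filled.grid[mask], em.grid[mask])
        # filled values are in the plausible range of their neighbours
        new = in_disk & ~mask
        assert np.all((filled.grid[new] > 5) & (filled.grid[new] < 15))
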