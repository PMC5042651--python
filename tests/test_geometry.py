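"""Geometry layer: alignment, egg-shell hull, distances, ROI sectioning."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from trimesh.proximity import closest_point_naive

from gastrumorph import geometry
from gastrumorph.errors import AnalysisError, GeometryError
from gastrumorph.geometry import (
    ROISpec,
    SurfaceMesh,
    align_embryo,
    build_egg_shell,
    encloses,
    point_mesh_distance,
    points_mesh_distance,
    section_slabs,
    vertex_normals,
)


def ellipsoid_cloud(rng, n=120, axes=(60.0, 35.0, 30.0)):
    """Points on an ellipsoid surface (nucleus-shell-like cloud)."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * np.asarray(axes)


class TestAlignEmbryo:
    def test_already_aligned_synthetic_embryo_is_near_identity(self, small_invagination):
        records, _ = small_invagination
        pts = np.vstack([r.centroid for r in records])
        rot, center, aligned = align_embryo(pts)
        # up to AP sign, the rotation should be the identity
        assert np.allclose(np.abs(np.diag(rot)), 1.0, atol=1e-2)
        assert np.allclose(rot @ rot.T, np.eye(3), atol=1e-12)

    def test_rotation_about_z_is_recovered(self, small_invagination):
        records, _ = small_invagination
        pts = np.vstack([r.centroid for r in records])
        ang = np.deg2rad(30)
        rz = np.array(
            [
                [np.cos(ang), -np.sin(ang), 0],
                [np.sin(ang), np.cos(ang), 0],
                [0, 0, 1],
            ]
        )
        rot, _, aligned = align_embryo(pts @ rz.T)
        _, _, ref = align_embryo(pts)
        assert np.allclose(aligned, ref, atol=1e-6)

    def test_two_points_raise(self):
        with pytest.raises(GeometryError):
            align_embryo(np.array([[0.0, 0, 0], [1, 0, 0]]))

    def test_collinear_cloud_raises(self):
        pts = np.outer(np.linspace(0, 1, 30), [1.0, 2.0, 3.0])
        with pytest.raises(GeometryError):
            align_embryo(pts)


class TestEggShell:
    def test_cube_corner_expansion(self):
        corners = np.array(
            [[x, y, z] for x in (0, 10.0) for y in (0, 10.0) for z in (0, 10.0)]
        )
        mesh = build_egg_shell(corners, nucleus_diameter=2.0)
        # ventral (bottom) corners move outward by exactly one radius; all
        # original corners end up inside, about one radius from the surface
        assert encloses(mesh, corners).all()
        d = points_mesh_distance(corners, mesh)
        bottom = corners[:, 2] == 0
        assert np.all(d[bottom] > 0.4) and np.all(d[bottom] < 1.01)

    def test_expansion_magnitude_is_half_nucleus_diameter(self, rng):
        pts = ellipsoid_cloud(rng, 150)
        d_nuc = 8.0
        hull = geometry._convex_hull_mesh(pts)
        expanded = build_egg_shell(pts, d_nuc)
        vn = vertex_normals(hull)
        ventral = vn[:, 2] < 0
        disp = np.linalg.norm(expanded.vertices - hull.vertices, axis=1)
        assert np.allclose(disp[ventral], d_nuc / 2, rtol=0.01)
        assert np.allclose(disp[~ventral], 0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_enclosure_of_random_clouds(self, seed):
        rng = np.random.default_rng(seed)
        if seed % 2:
            pts = ellipsoid_cloud(rng, 80)
        else:
            pts = rng.uniform(-30, 30, (60, 3))
        mesh = build_egg_shell(pts, nucleus_diameter=6.0)
        assert encloses(mesh, pts).all()

    def test_coplanar_cloud_raises(self):
        pts = np.c_[np.random.default_rng(0).uniform(0, 10, (20, 2)), np.zeros(20)]
        with pytest.raises(GeometryError):
            build_egg_shell(pts, 5.0)

    def test_alpha_hull_with_finite_probe_encloses_sphere_cloud(self, rng):
        pts = ellipsoid_cloud(rng, 200, axes=(20.0, 20.0, 20.0))
        mesh = build_egg_shell(pts, 4.0, alpha_probe_radius=30.0)
        assert encloses(mesh, pts * 0.9).all()

    def test_alpha_hull_tiny_probe_raises(self, rng):
        pts = ellipsoid_cloud(rng, 100, axes=(20.0, 20.0, 20.0))
        with pytest.raises(GeometryError):
            build_egg_shell(pts, 4.0, alpha_probe_radius=0.5)


class TestPointMeshDistance:
    def unit_triangle(self):
        return SurfaceMesh(
            np.array([[-1.0, -1, 0], [1.0, -1, 0], [0.0, 1.5, 0]]),
            np.array([[0, 1, 2]]),
        )

    def test_point_above_triangle_interior(self):
        assert point_mesh_distance([0.0, 0.0, 5.0], self.unit_triangle()) == pytest.approx(5.0)

    def test_point_above_edge_midpoint(self):
        # above the midpoint of the edge from (-1,-1) to (1,-1), offset 3 um
        # outward in -y so the closest feature is the edge itself
        assert point_mesh_distance([0.0, -4.0, 0.0], self.unit_triangle()) == pytest.approx(3.0)

    def test_empty_mesh_raises(self):
        mesh = SurfaceMesh(np.zeros((3, 3)), np.empty((0, 3), dtype=int))
        with pytest.raises(ValueError):
            point_mesh_distance([0, 0, 0.0], mesh)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_triangle_oracle(self, seed):
        rng = np.random.default_rng(seed)
        verts = rng.normal(0, 10, (25, 3))
        faces = rng.integers(0, 25, (60, 3))
        ok = (
            (faces[:, 0] != faces[:, 1])
            & (faces[:, 1] != faces[:, 2])
            & (faces[:, 0] != faces[:, 2])
        )
        mesh = SurfaceMesh(verts, faces[ok])
        pts = rng.normal(0, 12, (100, 3))
        mine = points_mesh_distance(pts, mesh)
        _, oracle, _ = closest_point_naive(mesh.to_trimesh(), pts)
        assert np.allclose(mine, oracle, atol=1e-9)

    def test_pruned_large_mesh_matches_oracle(self, rng):
        import trimesh

        ball = trimesh.creation.icosphere(4)  # > 4096 faces: pruning path
        mesh = SurfaceMesh(ball.vertices * 20, ball.faces)
        pts = rng.normal(0, 25, (50, 3))
        mine = points_mesh_distance(pts, mesh)
        _, oracle, _ = closest_point_naive(mesh.to_trimesh(), pts)
        assert np.allclose(mine, oracle, atol=1e-9)


class TestSectionSlabs:
    def uniform_roi_points(self, n=270, length=200.0):
        rng = np.random.default_rng(0)
        # ventral strip: x uniform, small angular spread around the midline
        x = rng.uniform(-length / 2, length / 2, n)
        y = rng.uniform(-5, 5, n)
        z = np.full(n, -40.0)
        return np.c_[x, y, z]

    def test_uniform_points_give_about_30_per_slab(self):
        pts = self.uniform_roi_points()
        roi = ROISpec(ap_fraction_bounds=(0.0, 1.0), n_sections=9)
        slabs = section_slabs(pts, roi)
        counts = [len(s.indices) for s in slabs]
        assert sum(counts) == 270
        assert all(15 <= c <= 45 for c in counts)

    def test_boundary_nucleus_goes_to_lower_slab(self):
        pts = np.array([[0.0, 0, -1], [10.0, 0, -1], [20.0, 0, -1], [5.0, 0, -1]])
        roi = ROISpec(ap_fraction_bounds=(0.0, 1.0), n_sections=2)
        slabs = section_slabs(pts, roi, ap_extent=(0.0, 20.0))
        # x = 10 is exactly the internal boundary -> lower-AP slab
        assert 1 in slabs[0].indices.tolist()
        assert len(slabs[0].indices) == 3 and len(slabs[1].indices) == 1

    def test_slab_width_arithmetic(self):
        pts = self.uniform_roi_points(50, 200.0)
        roi = ROISpec(ap_fraction_bounds=(0.25, 0.75), n_sections=9)
        slabs = section_slabs(pts, roi, ap_extent=(-100.0, 100.0))
        widths = [s.ap_hi - s.ap_lo for s in slabs]
        assert np.allclose(widths, 0.5 * 200.0 / 9)

    def test_empty_roi_raises(self):
        pts = np.array([[0.0, 0, 40.0]] * 5)  # dorsal side only
        with pytest.raises(AnalysisError):
            section_slabs(pts, ROISpec(), ap_extent=(-100, 100.0))

    @given(st.integers(0, 10_000))
    def test_partition_is_exhaustive_and_disjoint(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 80))
        pts = np.c_[
            rng.uniform(-90, 90, n),
            rng.uniform(-10, 10, n),
            rng.uniform(-45, -35, n),
        ]
        roi = ROISpec(n_sections=int(rng.integers(1, 12)))
        slabs = section_slabs(pts, roi, ap_extent=(-100.0, 100.0), cross_center=(0.0, 0.0))
        all_idx = np.concatenate([s.indices for s in slabs])
        assert len(all_idx) == len(set(all_idx.tolist()))
        mask = geometry.select_roi(pts, roi, ap_extent=(-100.0, 100.0))
        assert set(all_idx.tolist()) == set(np.nonzero(mask)[0].tolist())
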