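"""Centerline extraction: tube cues, shortest path, frames.

The Dijkstra oracle enumerates simple paths exhaustively on tiny grids.
"""

import itertools

import numpy as np
import pytest
from scipy.spatial import cKDTree

from aortacontour.centerline import (ScalarMap, cost_image, dijkstra_path,
                                     hough_circle_map, resample_centerline,
                                     vesselness, compute_centerline)
from aortacontour.imaging import ImageVolume


def scalar_map(values, spacing=1.0):
    return ScalarMap(values=np.asarray(values, dtype=float),
                     spacing=np.full(3, spacing), origin=np.zeros(3),
                     direction=np.eye(3))


def brute_force_min_cost(vals, spacing, start, end=None):
    """Exhaustive relaxation (Bellman-Ford) over the 26-connected grid.

    Repeats full edge relaxation |V| times, so it provably reaches the
    minimum over all paths without any priority-queue logic; independent of
    the Dijkstra implementation under test.  Returns the distance map from
    ``start`` (or the single distance to ``end``).
    """
    shape = vals.shape
    offs = [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    steps = {o: np.linalg.norm(np.asarray(o) * spacing) for o in offs}
    dist = np.full(shape, np.inf)
    dist[start] = 0.0
    n = vals.size
    for _ in range(n):
        changed = False
        for node in np.ndindex(shape):
            d = dist[node]
            if not np.isfinite(d):
                continue
            for o in offs:
                nb = tuple(np.asarray(node) + o)
                if any(c < 0 or c >= s for c, s in zip(nb, shape)):
                    continue
                nd = d + vals[nb] * steps[o]
                if nd < dist[nb] - 1e-15:
                    dist[nb] = nd
                    changed = True
        if not changed:
            break
    if end is None:
        return dist
    return dist[end]


class TestVesselness:
    def test_constant_image_zero_response(self):
        vol = ImageVolume(values=np.full((20, 20, 20), 5.0), spacing=np.ones(3),
                          origin=np.zeros(3), direction=np.eye(3))
        v = vesselness(vol, scales_mm=[2.0])
        assert np.allclose(v.values, 0.0)

    def test_anisotropic_input_rejected(self):
        vol = ImageVolume(values=np.zeros((10, 10, 10)),
                          spacing=np.array([0.5, 0.5, 1.0]),
                          origin=np.zeros(3), direction=np.eye(3))
        with pytest.raises(ValueError, match="isotropic"):
            vesselness(vol, scales_mm=[2.0])

    def test_tube_centerline_outshines_background(self, soft_cylinder_phantom):
        ph = soft_cylinder_phantom
        v = vesselness(ph.image, scales_mm=[6.0, 8.0, 10.0])
        cl_resp = v.sample(ph.truth_centerline.points[10:-10])
        # background: a shell far outside the tube
        far = ph.truth_centerline.points[len(ph.truth_centerline) // 2] + [18.0, 0, 0]
        bg = v.sample(far[None, :] + np.random.default_rng(0).normal(0, 1, (50, 3)))
        assert np.median(cl_resp) > 10 * np.mean(np.abs(bg))

    def test_blob_suppressed_relative_to_tube(self, soft_cylinder_phantom):
        # a solid ball is a blob, not a tube: Frangi suppresses its centre
        n = 48
        g = (np.arange(n) - n / 2) * 1.0
        gx, gy, gz = np.meshgrid(g, g, g, indexing="ij")
        ball = (np.sqrt(gx**2 + gy**2 + gz**2) <= 18).astype(float) * 400
        from scipy.ndimage import gaussian_filter

        vol = ImageVolume(values=gaussian_filter(ball, 1.0), spacing=np.ones(3),
                          origin=np.zeros(3), direction=np.eye(3))
        v = vesselness(vol, scales_mm=[4.0, 6.0])
        center_resp = v.values[n // 2, n // 2, n // 2]
        tube = soft_cylinder_phantom
        vt = vesselness(tube.image, scales_mm=[6.0, 8.0])
        tube_resp = np.median(vt.sample(tube.truth_centerline.points[10:-10]))
        assert center_resp < 0.1 * tube_resp


class TestHough:
    @staticmethod
    def _disk_volume(radius_mm=8.0, n=64, spacing=1.0, center=(32, 32)):
        vals = np.zeros((n, n, 5))
        g = np.arange(n) * spacing
        gx, gy = np.meshgrid(g, g, indexing="ij")
        disk = ((gx - center[0]) ** 2 + (gy - center[1]) ** 2) <= radius_mm**2
        vals[:, :, 2] = disk * 100.0
        return ImageVolume(values=vals, spacing=np.full(3, spacing),
                           origin=np.zeros(3), direction=np.eye(3))

    def test_disk_center_is_accumulator_argmax(self):
        vol = self._disk_volume()
        h = hough_circle_map(vol, radius_range_mm=(5, 12), axis=2)
        sl = h.values[:, :, 2]
        peak = np.unravel_index(np.argmax(sl), sl.shape)
        assert abs(peak[0] - 32) <= 1 and abs(peak[1] - 32) <= 1

    def test_constant_image_all_zero(self):
        vol = ImageVolume(values=np.full((30, 30, 4), 9.0), spacing=np.ones(3),
                          origin=np.zeros(3), direction=np.eye(3))
        h = hough_circle_map(vol, radius_range_mm=(3, 8), axis=2)
        assert np.allclose(h.values, 0.0)

    def test_two_disks_two_local_maxima(self):
        n = 96
        vals = np.zeros((n, n, 3))
        g = np.arange(n) * 1.0
        gx, gy = np.meshgrid(g, g, indexing="ij")
        for cx, cy in ((25, 25), (70, 70)):
            vals[:, :, 1] += (((gx - cx) ** 2 + (gy - cy) ** 2) <= 64) * 100.0
        vol = ImageVolume(values=vals, spacing=np.ones(3), origin=np.zeros(3),
                          direction=np.eye(3))
        h = hough_circle_map(vol, radius_range_mm=(5, 12), axis=2)
        sl = h.values[:, :, 1]
        assert sl[25, 25] > 0.5 * sl.max()
        assert sl[70, 70] > 0.5 * sl.max()

    def test_empty_radius_range_rejected(self):
        vol = self._disk_volume()
        with pytest.raises(ValueError):
            hough_circle_map(vol, radius_range_mm=(8, 8), axis=2)


class TestCostImage:
    def test_formula_extremes_and_monotonicity(self):
        v = scalar_map(np.array([[[1.0, 0.0, 0.3]]]))
        h = scalar_map(np.array([[[1.0, 0.0, 0.3]]]))
        c = cost_image(v, h, eps=1e-3)
        assert np.isclose(c.values[0, 0, 0], 1e-3)
        assert np.isclose(c.values[0, 0, 1], 1.0 + 1e-3)
        # monotone non-increasing in v at fixed h
        v2 = scalar_map(np.array([[[1.0, 0.1, 0.4]]]))
        c2 = cost_image(v2, h, eps=1e-3)
        assert c2.values[0, 0, 2] <= c.values[0, 0, 2]

    def test_geometry_mismatch_rejected(self):
        v = scalar_map(np.zeros((2, 2, 2)))
        h = scalar_map(np.zeros((3, 2, 2)))
        with pytest.raises(ValueError, match="geometry"):
            cost_image(v, h)


class TestDijkstra:
    def test_uniform_cost_straight_path(self):
        vals = np.ones((7, 3, 3))
        cmap = scalar_map(vals)
        path, total = dijkstra_path(cmap, np.array([0.0, 1, 1]),
                                    np.array([6.0, 1, 1]), return_cost=True)
        assert np.allclose(path[:, 1:], 1.0)
        assert np.isclose(total, 6.0)

    def test_wall_with_gap_matches_brute_force(self):
        rng = np.random.default_rng(0)
        vals = np.ones((5, 5, 1)) * 0.2
        vals[2, :, 0] = 50.0
        vals[2, 3, 0] = 0.2  # the gap
        cmap = scalar_map(vals)
        start, end = (0, 0, 0), (4, 0, 0)
        path, total = dijkstra_path(cmap, cmap.index_to_world(np.array(start)),
                                    cmap.index_to_world(np.array(end)),
                                    return_cost=True)
        assert any(np.allclose(p, cmap.index_to_world(np.array([2, 3, 0]))) for p in path)
        oracle = brute_force_min_cost(vals, np.ones(3), start, end)
        assert np.isclose(total, oracle, atol=1e-9)

    def test_random_grid_all_pairs_optimality(self):
        """Path cost equals exhaustive minimum on a seeded 5x5x3 grid."""
        rng = np.random.default_rng(42)
        vals = rng.uniform(0.1, 2.0, size=(5, 5, 3))
        cmap = scalar_map(vals)
        corners = [(0, 0, 0), (4, 4, 2), (0, 4, 2), (4, 0, 1)]
        for start, end in itertools.combinations(corners, 2):
            _, total = dijkstra_path(cmap, cmap.index_to_world(np.array(start)),
                                     cmap.index_to_world(np.array(end)),
                                     return_cost=True)
            oracle = brute_force_min_cost(vals, np.ones(3), start, end)
            assert np.isclose(total, oracle, atol=1e-9)

    def test_cost_scaling_preserves_path(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.1, 1.0, size=(6, 4, 2))
        cmap = scalar_map(vals)
        s, e = np.array([0.0, 0, 0]), np.array([5.0, 3, 1])
        p1, t1 = dijkstra_path(cmap, s, e, return_cost=True)
        cmap2 = scalar_map(vals * 3.0)
        p2, t2 = dijkstra_path(cmap2, s, e, return_cost=True)
        assert np.allclose(p1, p2)
        assert np.isclose(t2, 3.0 * t1)

    def test_unreachable_end_raises(self):
        vals = np.ones((5, 1, 1))
        vals[2] = np.inf
        cmap = scalar_map(vals)
        with pytest.raises(ValueError, match="unreachable"):
            dijkstra_path(cmap, np.zeros(3), np.array([4.0, 0, 0]))


class TestResampleCenterline:
    def test_collinear_points_constant_frames(self):
        pts = np.stack([np.zeros(10), np.zeros(10), np.linspace(0, 20, 10)], axis=1)
        cl = resample_centerline(pts, step_mm=1.0)
        line_dev = np.linalg.norm(cl.points[:, :2], axis=1)
        assert line_dev.max() < 1e-9
        assert np.allclose(cl.frames, cl.frames[0], atol=1e-9)

    def test_uniform_arclength_steps(self):
        theta = np.linspace(0, np.pi / 2, 30)
        pts = np.stack([20 * np.cos(theta), 20 * np.sin(theta), np.zeros(30)], axis=1)
        cl = resample_centerline(pts, step_mm=1.0)
        steps = np.diff(cl.arclengths)
        assert np.allclose(steps[:-1], 1.0, atol=1e-3)

    def test_quarter_circle_arclength(self):
        theta = np.linspace(0, np.pi / 2, 50)
        pts = np.stack([20 * np.cos(theta), 20 * np.sin(theta), np.zeros(50)], axis=1)
        cl = resample_centerline(pts, step_mm=0.5)
        assert cl.arclengths[-1] == pytest.approx(np.pi * 20 / 2, rel=0.01)

    def test_planar_curve_accumulates_no_twist(self):
        # rotation-minimizing frames on a planar curve keep the out-of-plane
        # axis fixed: accumulated twist about the tangent is ~0
        theta = np.linspace(0, np.pi / 2, 50)
        pts = np.stack([20 * np.cos(theta), 20 * np.sin(theta), np.zeros(50)], axis=1)
        cl = resample_centerline(pts, step_mm=0.5)
        out_of_plane = np.abs(cl.frames @ np.array([0.0, 0.0, 1.0]))
        # one frame axis stays aligned with z throughout
        aligned = np.max(out_of_plane, axis=1)
        assert np.all(aligned > 1 - 1e-3)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            resample_centerline(np.zeros((5, 3)))

    def test_frames_orthonormal(self):
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.normal(0, 1, (20, 3)) + [0, 0, 2.0], axis=0)
        cl = resample_centerline(pts, step_mm=1.0)
        for i in range(len(cl)):
            t, u, v = cl.tangents[i], cl.frames[i, 0], cl.frames[i, 1]
            gram = np.array([[t @ t, t @ u, t @ v], [u @ t, u @ u, u @ v],
                             [v @ t, v @ u, v @ v]])
            assert np.allclose(gram, np.eye(3), atol=1e-9)


class TestFullCenterline:
    def test_recovers_truth_centerline_on_noise_free_tube(self, soft_cylinder_phantom):
        ph = soft_cylinder_phantom
        cl = compute_centerline(ph.image, ph.landmarks)
        d, _ = cKDTree(ph.truth_centerline.points).query(cl.points)
        assert d.max() < 2 * ph.image.spacing[0]
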