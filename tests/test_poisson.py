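"""Screened Poisson reconstruction: field solve, isosurface, voxelization,
centerline clipping."""

import numpy as np
import pytest

from aortacontour.centerline import resample_centerline
from aortacontour.contours import OrientedPointCloud
from aortacontour.imaging import BinaryMask, ImageVolume
from aortacontour.poisson import (ImplicitField, PoissonParams, SurfaceMesh,
                                  clip_mask, extract_isosurface,
                                  reconstruct_field, voxelize)
from conftest import make_cylinder_mask


def sphere_cloud(n=2000, radius=10.0, seed=0, flip=False):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    normals = -v if flip else v
    return OrientedPointCloud(points=radius * v, normals=normals)


@pytest.fixture(scope="module")
def sphere_field():
    return reconstruct_field(sphere_cloud(), PoissonParams(depth=6))


class TestReconstructField:
    def test_sphere_isosurface_radius(self, sphere_field):
        mesh = extract_isosurface(sphere_field)
        r = np.linalg.norm(mesh.vertices, axis=1)
        assert np.abs(r - 10.0).mean() < sphere_field.spacing

    def test_flipped_normals_negate_field(self):
        params = PoissonParams(depth=5)
        f1 = reconstruct_field(sphere_cloud(n=500), params)
        f2 = reconstruct_field(sphere_cloud(n=500, flip=True), params)
        # fields are defined up to the screening-induced offset; compare
        # after removing the mean
        a = f1.values - f1.values.mean()
        b = f2.values - f2.values.mean()
        assert np.allclose(a, -b, atol=5e-3 * np.abs(a).max() + 1e-6)

    def test_screening_pulls_samples_to_isovalue(self):
        cloud = sphere_cloud(n=800)
        devs = []
        for w in (0.0, 4.0, 40.0):
            f = reconstruct_field(cloud, PoissonParams(depth=5, screening_weight=w))
            devs.append(np.abs(f.sample(cloud.points) - f.isovalue).mean())
        assert devs[0] >= devs[1] >= devs[2]

    def test_energy_local_optimality(self):
        """The returned field beats random perturbations of itself on the
        discrete screened-Poisson energy."""
        from aortacontour.poisson import (_gradient_operator, _grid_geometry,
                                          _splat_normal_field, _trilinear_weights)

        cloud = sphere_cloud(n=300, radius=8.0)
        params = PoissonParams(depth=4)
        field = reconstruct_field(cloud, params)
        dims, h, origin = _grid_geometry(cloud.points, params)
        grads = _gradient_operator(dims, h)
        V = _splat_normal_field(cloud, dims, h, origin, params.samples_per_node)
        P = _trilinear_weights(cloud.points, origin, h, dims)

        def energy(chi_flat):
            e = 0.0
            for a in range(3):
                sl_lo = [slice(None)] * 3
                sl_hi = [slice(None)] * 3
                sl_lo[a] = slice(0, -1)
                sl_hi[a] = slice(1, None)
                v_edge = 0.5 * (V[a][tuple(sl_lo)] + V[a][tuple(sl_hi)]).ravel()
                e += float(np.sum((grads[a] @ chi_flat - v_edge) ** 2)) * h**3
            e += params.screening_weight / len(cloud.points) * float(
                np.sum((P @ chi_flat) ** 2))
            return e

        chi = field.values.ravel()
        e0 = energy(chi)
        rng = np.random.default_rng(1)
        scale = np.abs(chi).max()
        for _ in range(200):
            pert = rng.normal(0, 1e-3 * scale, size=chi.shape)
            assert energy(chi + pert) >= e0 - 1e-9 * max(e0, 1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="100"):
            reconstruct_field(sphere_cloud(n=50), PoissonParams(depth=4))

    def test_param_validation(self):
        with pytest.raises(ValueError):
            PoissonParams(depth=3)
        with pytest.raises(ValueError):
            PoissonParams(screening_weight=-1)
        with pytest.raises(ValueError):
            PoissonParams(bbox_scale=0.5)


def sphere_sdf_field(radius=10.0, n=41, spacing=0.6):
    c = (n - 1) / 2 * spacing
    ax = np.arange(n) * spacing
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    d = np.sqrt((gx - c) ** 2 + (gy - c) ** 2 + (gz - c) ** 2) - radius
    return ImplicitField(values=d, spacing=spacing,
                         origin=np.zeros(3), isovalue=0.0), np.array([c, c, c])


class TestExtractIsosurface:
    def test_sdf_sphere_vertex_radii(self):
        field, center = sphere_sdf_field()
        mesh = extract_isosurface(field)
        r = np.linalg.norm(mesh.vertices - center, axis=1)
        assert np.all(np.abs(r - 10.0) <= field.spacing / 2 + 1e-9)

    def test_level_set_scale_invariance(self):
        field, _ = sphere_sdf_field()
        scaled = ImplicitField(values=field.values * 2.0, spacing=field.spacing,
                               origin=field.origin, isovalue=0.0)
        m1 = extract_isosurface(field)
        m2 = extract_isosurface(scaled)
        assert np.allclose(m1.vertices, m2.vertices, atol=1e-9)
        assert np.array_equal(m1.faces, m2.faces)

    def test_largest_component_kept(self):
        f1, c1 = sphere_sdf_field(radius=10.0, n=61)
        # add a smaller distant blob
        ax = np.arange(61) * 0.6
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        blob = np.sqrt((gx - 3) ** 2 + (gy - 3) ** 2 + (gz - 3) ** 2) - 2.0
        twin = ImplicitField(values=np.minimum(f1.values, blob), spacing=0.6,
                             origin=np.zeros(3), isovalue=0.0)
        mesh = extract_isosurface(twin)
        r = np.linalg.norm(mesh.vertices - c1, axis=1)
        assert np.all(np.abs(r - 10.0) < 1.0)   # only the big sphere remains

    def test_isovalue_outside_range_rejected(self):
        field, _ = sphere_sdf_field()
        bad = ImplicitField(values=field.values, spacing=field.spacing,
                            origin=field.origin, isovalue=1e6)
        with pytest.raises(ValueError, match="isovalue"):
            extract_isosurface(bad)


class TestVoxelize:
    @staticmethod
    def _sphere_mesh(radius=10.0, spacing=0.4):
        field, center = sphere_sdf_field(radius=radius, n=int(28 / spacing) | 1,
                                         spacing=spacing)
        return extract_isosurface(field), center

    def test_sphere_volume_within_2pct(self):
        mesh, _ = self._sphere_mesh()
        ref = ImageVolume(values=np.zeros((60, 60, 60)), spacing=np.full(3, 0.5),
                          origin=np.full(3, -1.0), direction=np.eye(3))
        mask = voxelize(mesh, ref)
        vol = mask.foreground_count * 0.5**3
        assert vol == pytest.approx(4 / 3 * np.pi * 10**3, rel=0.02)

    def test_mesh_outside_grid_gives_empty_mask(self):
        mesh, _ = self._sphere_mesh()
        ref = ImageVolume(values=np.zeros((20, 20, 20)), spacing=np.ones(3),
                          origin=np.full(3, 500.0), direction=np.eye(3))
        mask = voxelize(mesh, ref)
        assert mask.foreground_count == 0

    def test_voxelize_extract_voxelize_stable(self):
        from aortacontour.evaluate import dice

        mesh, _ = self._sphere_mesh()
        ref = ImageVolume(values=np.zeros((70, 70, 70)), spacing=np.full(3, 0.4),
                          origin=np.full(3, -0.8), direction=np.eye(3))
        m1 = voxelize(mesh, ref)
        field2 = ImplicitField(values=0.5 - m1.values.astype(float), spacing=0.4,
                               origin=ref.origin, isovalue=0.0)
        mesh2 = extract_isosurface(field2)
        m2 = voxelize(mesh2, ref)
        assert dice(m1, m2) >= 0.98

    def test_open_mesh_rejected(self):
        # a single triangle is maximally open
        mesh = SurfaceMesh(vertices=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]),
                           faces=np.array([[0, 1, 2]]))
        ref = ImageVolume(values=np.zeros((5, 5, 5)), spacing=np.ones(3),
                          origin=np.zeros(3), direction=np.eye(3))
        with pytest.raises(ValueError, match="watertight"):
            voxelize(mesh, ref)


class TestClipMask:
    @staticmethod
    def _cyl_and_cl():
        mask = make_cylinder_mask(radius_mm=8.0, height_mm=40.0, spacing=0.5)
        pts = np.stack([np.zeros(9), np.zeros(9), np.linspace(0, 40, 9)], axis=1)
        return mask, resample_centerline(pts, step_mm=1.0)

    def test_full_range_is_identity(self):
        mask, cl = self._cyl_and_cl()
        out = clip_mask(mask, cl, 0.0, cl.arclengths[-1])
        assert np.array_equal(out.values, mask.values)

    def test_middle_half_keeps_half_volume(self):
        mask, cl = self._cyl_and_cl()
        out = clip_mask(mask, cl, 10.0, 30.0)
        assert out.foreground_count == pytest.approx(mask.foreground_count / 2,
                                                     rel=0.05)

    def test_retained_voxels_project_into_range(self):
        mask, cl = self._cyl_and_cl()
        out = clip_mask(mask, cl, 12.0, 28.0)
        fg = np.argwhere(out.values > 0)
        s = cl.project(out.index_to_world(fg))
        assert s.min() >= 12.0 - out.spacing[0] - 1e-9
        assert s.max() <= 28.0 + out.spacing[0] + 1e-9

    def test_invalid_range_rejected(self):
        mask, cl = self._cyl_and_cl()
        with pytest.raises(ValueError):
            clip_mask(mask, cl, 30.0, 10.0)
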