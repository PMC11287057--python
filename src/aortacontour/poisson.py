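"""Screened Poisson surface reconstruction on a regular grid.

Given an oriented point cloud (contour points with outward in-plane
normals), the reconstruction finds a scalar field chi whose gradient matches
the smoothed normal field V splatted from the samples, with an additional
value ("screening") penalty that pulls the field toward the isovalue at the
sample points:

    E(chi) = integral ||grad chi - V||^2 dx + (lambda/N) * sum_i chi(p_i)^2

under zero-Neumann boundary conditions.  The discrete Euler-Lagrange system
is the screened Poisson equation, solved by conjugate gradients; the
isosurface at the mean field value over the samples is the reconstructed
boundary.  Default parameters follow the screened-Poisson convention:
screening weight 4, bounding-box scale 1.1, one sample per node, and a grid
refinement depth giving 2^depth cells along the longest bounding-box axis
(the regular-grid counterpart of an octree depth).

The contour stack bounds an open tube, while the Poisson formulation wants a
closed normal field: synthetic cap-point rings with axial normals are added
at the first and last contour before solving, and the resulting caps are
trimmed off again by clipping the mask along the centerline.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter
from scipy.sparse.linalg import cg
from skimage import measure

from .centerline import Centerline
from .contours import ContourStack, OrientedPointCloud, stack_to_point_cloud
from .imaging import BinaryMask, ImageVolume

__all__ = [
    "PoissonParams",
    "ImplicitField",
    "SurfaceMesh",
    "reconstruct_field",
    "extract_isosurface",
    "voxelize",
    "clip_mask",
    "add_end_caps",
    "reconstruct_mask",
]


@dataclasses.dataclass
class PoissonParams:
    screening_weight: float = 4.0
    bbox_scale: float = 1.1
    samples_per_node: float = 1.0
    depth: int = 7
    isovalue_mode: str = "mean_at_samples"

    def __post_init__(self) -> None:
        if self.screening_weight < 0:
            raise ValueError("screening_weight must be >= 0")
        if self.bbox_scale < 1:
            raise ValueError("bbox_scale must be >= 1")
        if not 4 <= self.depth <= 9:
            raise ValueError("depth must be in [4, 9]")
        if self.isovalue_mode not in ("mean_at_samples", "zero"):
            raise ValueError("isovalue_mode must be 'mean_at_samples' or 'zero'")


@dataclasses.dataclass
class ImplicitField:
    values: np.ndarray       # node-centred field, shape (nx, ny, nz)
    spacing: float           # isotropic cell size, mm
    origin: np.ndarray       # world mm of node (0, 0, 0)
    isovalue: float

    def sample(self, points: np.ndarray) -> np.ndarray:
        from scipy.ndimage import map_coordinates

        idx = (np.asarray(points, dtype=float) - self.origin) / self.spacing
        return map_coordinates(self.values, idx.reshape(-1, 3).T, order=1,
                               mode="nearest").reshape(np.asarray(points).shape[:-1])


@dataclasses.dataclass
class SurfaceMesh:
    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("faces reference invalid vertices")

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @property
    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def export(self, path) -> None:
        self.to_trimesh().export(str(path))


# -- energy pieces ---------------------------------------------------------


def _grid_geometry(points: np.ndarray, params: PoissonParams):
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    center = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo) * params.bbox_scale
    half = np.maximum(half, 1e-6)
    h = 2.0 * half.max() / (2 ** params.depth)
    dims = np.maximum(np.ceil(2 * half / h).astype(int) + 1, 2)
    origin = center - (dims - 1) * h / 2.0
    return dims, h, origin


def _trilinear_weights(points: np.ndarray, origin: np.ndarray, h: float, dims):
    """Sparse sampling matrix P with P @ chi = trilinear chi at the points."""
    n = len(points)
    f = (points - origin) / h
    i0 = np.floor(f).astype(int)
    i0 = np.clip(i0, 0, np.asarray(dims) - 2)
    t = f - i0
    rows, cols, data = [], [], []
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (t[:, 0] if dx else 1 - t[:, 0])
                    * (t[:, 1] if dy else 1 - t[:, 1])
                    * (t[:, 2] if dz else 1 - t[:, 2])
                )
                node = np.ravel_multi_index(
                    (i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz), dims
                )
                rows.append(np.arange(n))
                cols.append(node)
                data.append(w)
    return sparse.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, int(np.prod(dims))),
    )


def _gradient_operator(dims, h: float):
    """Forward-difference gradient; natural BC of the least-squares problem
    is zero-Neumann."""
    nx, ny, nz = dims
    n = nx * ny * nz

    def diff_axis(axis: int):
        shape_m = list(dims)
        shape_m[axis] -= 1
        idx = np.indices(shape_m).reshape(3, -1)
        lo = np.ravel_multi_index(idx, dims)
        idx_hi = idx.copy()
        idx_hi[axis] += 1
        hi = np.ravel_multi_index(idx_hi, dims)
        m = lo.size
        rows = np.concatenate([np.arange(m), np.arange(m)])
        cols = np.concatenate([hi, lo])
        data = np.concatenate([np.full(m, 1.0 / h), np.full(m, -1.0 / h)])
        return sparse.csr_matrix((data, (rows, cols)), shape=(m, n))

    return [diff_axis(a) for a in range(3)]


def _splat_normal_field(cloud: OrientedPointCloud, dims, h: float,
                        origin: np.ndarray, sigma_cells: float) -> np.ndarray:
    """Trilinear splat of the normals onto grid nodes + Gaussian smoothing,
    approximating the smoothed indicator gradient; normalized so the field
    integrates like a surface-delta of unit magnitude per sample area."""
    P = _trilinear_weights(cloud.points, origin, h, dims)
    V = np.stack(
        [(P.T @ cloud.normals[:, a]).reshape(dims) for a in range(3)], axis=0
    )
    if sigma_cells > 0:
        for a in range(3):
            V[a] = gaussian_filter(V[a], sigma=sigma_cells, mode="constant")
    # scale: each sample represents ~ (spacing between samples)^2 of surface
    # area; the smoothed gradient of a unit indicator integrates to 1 across
    # the surface, so scale splats from "per point" to "per volume" units
    n = len(cloud.points)
    area_per_pt = _estimate_area_per_point(cloud.points, n)
    V *= area_per_pt / h**3
    return V


def _estimate_area_per_point(points: np.ndarray, n: int) -> float:
    # median nearest-neighbour distance squared is a serviceable area quantum
    from scipy.spatial import cKDTree

    k = min(n, 2000)
    rng = np.random.default_rng(0)
    sel = rng.choice(n, size=k, replace=False) if n > k else np.arange(n)
    d, _ = cKDTree(points).query(points[sel], k=2)
    return float(np.median(d[:, 1]) ** 2)


def reconstruct_field(cloud: OrientedPointCloud, params: PoissonParams) -> ImplicitField:
    """Solve the screened Poisson system for the implicit field.

    The normal equations ``(h * L + (lambda/N) P^T P) chi = h * G^T v`` (L the
    7-point Laplacian from the forward-difference gradient, P trilinear
    sampling at the input points) are solved by conjugate gradients to a
    relative residual of 1e-6 (max 2000 iterations).
    """
    if len(cloud.points) < 100:
        raise ValueError("need at least 100 oriented points")
    if np.allclose(np.linalg.norm(cloud.normals, axis=1), 0):
        raise ValueError("all normals are zero: system is singular")
    dims, h, origin = _grid_geometry(cloud.points, params)
    grads = _gradient_operator(dims, h)
    V = _splat_normal_field(cloud, dims, h, origin, sigma_cells=params.samples_per_node)

    # edge-midpoint values of V along each axis (average of adjacent nodes)
    def edge_field(a: int) -> np.ndarray:
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[a] = slice(0, -1)
        sl_hi[a] = slice(1, None)
        return 0.5 * (V[a][tuple(sl_lo)] + V[a][tuple(sl_hi)])

    n_nodes = int(np.prod(dims))
    A = sparse.csr_matrix((n_nodes, n_nodes))
    b = np.zeros(n_nodes)
    for a in range(3):
        G = grads[a]
        A = A + (G.T @ G)
        b = b + G.T @ edge_field(a).ravel()
    A = A * h
    b = b * h
    lam = params.screening_weight
    P = _trilinear_weights(cloud.points, origin, h, dims)
    if lam > 0:
        A = A + (lam / len(cloud.points)) * (P.T @ P)

    x0 = np.zeros(n_nodes)
    chi, info = cg(A, b, x0=x0, rtol=1e-6, maxiter=2000)
    if info > 0:
        res = np.linalg.norm(A @ chi - b) / max(np.linalg.norm(b), 1e-30)
        raise RuntimeError(f"Poisson solver did not converge: relative residual {res:.2e}")
    chi = chi.reshape(dims)
    if params.isovalue_mode == "mean_at_samples":
        iso = float((P @ chi.ravel()).mean())
    else:
        iso = 0.0
    return ImplicitField(values=chi, spacing=h, origin=origin, isovalue=iso)


def extract_isosurface(field: ImplicitField) -> SurfaceMesh:
    """Marching cubes at the field's isovalue; largest component kept."""
    vals = field.values
    if not (vals.min() < field.isovalue < vals.max()):
        raise ValueError("isovalue outside the field's value range")
    # pad with an outside (above-isovalue) rind so the surface closes at the
    # grid boundary and the mesh stays watertight
    pad_val = float(vals.max()) + abs(field.isovalue) + 1.0
    padded = np.pad(vals, 1, constant_values=pad_val)
    verts, faces, _, _ = measure.marching_cubes(padded, level=field.isovalue)
    verts = (verts - 1.0) * field.spacing + field.origin
    mesh = SurfaceMesh(vertices=verts, faces=faces)
    tm = mesh.to_trimesh()
    comps = tm.split(only_watertight=False)
    if len(comps) > 1:
        comps = sorted(comps, key=lambda c: len(c.faces), reverse=True)
        tm = comps[0]
    return SurfaceMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))


def voxelize(mesh: SurfaceMesh, reference: ImageVolume) -> BinaryMask:
    """Binary mask of voxel centres inside a watertight mesh (ray parity).

    Crossing parity is counted along the third index axis: each triangle's
    crossing height is rasterized onto the in-plane pixel grid, and a voxel
    is inside when an odd number of crossings lies above its centre.
    """
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        edges = tm.edges_sorted
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        n_open = int((counts != 2).sum())
        raise ValueError(f"mesh is not watertight ({n_open} open edges)")

    shape = reference.shape
    # mesh vertices in continuous index coordinates of the reference grid
    vidx = reference.world_to_index(mesh.vertices)
    # deterministic sub-voxel jitter avoids rays through vertices/edges
    jitter = np.array([1.5e-4, 3.5e-4, 0.7e-4])
    vidx = vidx + jitter
    tri = vidx[mesh.faces]  # (T, 3, 3)

    crossings = np.zeros((shape[0], shape[1], shape[2] + 1), dtype=np.int64)
    x0, y0 = tri[:, :, 0], tri[:, :, 1]
    xmin = np.maximum(np.ceil(x0.min(axis=1)), 0).astype(int)
    xmax = np.minimum(np.floor(x0.max(axis=1)), shape[0] - 1).astype(int)
    ymin = np.maximum(np.ceil(y0.min(axis=1)), 0).astype(int)
    ymax = np.minimum(np.floor(y0.max(axis=1)), shape[1] - 1).astype(int)
    for t in range(len(tri)):
        if xmax[t] < xmin[t] or ymax[t] < ymin[t]:
            continue
        a, b, c = tri[t]
        xs = np.arange(xmin[t], xmax[t] + 1)
        ys = np.arange(ymin[t], ymax[t] + 1)
        px, py = np.meshgrid(xs, ys, indexing="ij")
        # barycentric coordinates in the (x, y) projection
        d = (b[1] - c[1]) * (a[0] - c[0]) + (c[0] - b[0]) * (a[1] - c[1])
        if abs(d) < 1e-12:
            continue
        w1 = ((b[1] - c[1]) * (px - c[0]) + (c[0] - b[0]) * (py - c[1])) / d
        w2 = ((c[1] - a[1]) * (px - c[0]) + (a[0] - c[0]) * (py - c[1])) / d
        w3 = 1.0 - w1 - w2
        hit = (w1 >= 0) & (w2 >= 0) & (w3 >= 0)
        if not hit.any():
            continue
        z = w1 * a[2] + w2 * b[2] + w3 * c[2]
        # a crossing at height z lies above voxel centres with index < z;
        # bin it at ceil(z) so the suffix sum from bin k+1 counts crossings
        # strictly above voxel k
        zbin = np.clip(np.ceil(z[hit]).astype(int), 0, shape[2])
        np.add.at(crossings, (px[hit], py[hit], zbin), 1)
    # voxel k is inside when the number of crossings above its centre is odd
    above = np.cumsum(crossings[:, :, ::-1], axis=2)[:, :, ::-1]
    inside = (above[:, :, 1:] % 2).astype(np.uint8)
    return BinaryMask(values=inside, spacing=reference.spacing,
                      origin=reference.origin, direction=reference.direction)


def clip_mask(mask: BinaryMask, cl: Centerline, s_start: float, s_end: float) -> BinaryMask:
    """Zero voxels whose nearest-centerline arclength lies outside [s_start, s_end]."""
    if not (0 <= s_start < s_end <= cl.arclengths[-1] + 1e-9):
        raise ValueError("clip range must satisfy 0 <= s_start < s_end <= length")
    fg = np.argwhere(mask.values > 0)
    if fg.size == 0:
        raise ValueError("mask is empty")
    world = mask.index_to_world(fg)
    s = cl.project(world)
    keep = (s >= s_start) & (s <= s_end)
    if not keep.any():
        raise ValueError("clip removed every voxel")
    out = np.zeros_like(mask.values)
    kept = fg[keep]
    out[kept[:, 0], kept[:, 1], kept[:, 2]] = 1
    return BinaryMask(values=out, spacing=mask.spacing,
                      origin=mask.origin, direction=mask.direction)


# -- tube capping and end-to-end helper ------------------------------------


def add_end_caps(cloud: OrientedPointCloud, stack: ContourStack) -> OrientedPointCloud:
    """Close the open tube with synthetic cap-point rings (axial normals).

    Concentric rings of points are added on the first and last contour
    planes with normals along the outward tube axis, so the Poisson normal
    field encloses a finite volume; the caps are later trimmed by
    ``clip_mask``.
    """
    pts = [cloud.points]
    nrm = [cloud.normals]
    for which, sign in ((0, -1.0), (-1, 1.0)):
        c = stack.contours[which]
        sec = c.section
        axis = sign * sec.normal / np.linalg.norm(sec.normal)
        radii2d = np.linalg.norm(c.points2d, axis=1)
        r_max = float(radii2d.mean())
        n_ring = len(c.points2d)
        for frac in (0.25, 0.5, 0.75, 0.95):
            r = frac * r_max
            k = max(int(round(n_ring * frac)), 8)
            th = np.arange(k) * (2 * np.pi / k)
            ring2d = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
            pts.append(sec.plane_to_world(ring2d))
            nrm.append(np.tile(axis, (k, 1)))
        pts.append(sec.origin[None, :])
        nrm.append(axis[None, :])
    return OrientedPointCloud(points=np.concatenate(pts), normals=np.concatenate(nrm))


def reconstruct_mask(
    stack: ContourStack,
    reference: ImageVolume,
    cl: Centerline,
    params: PoissonParams | None = None,
    clip_margin_mm: float = 0.5,
    return_mesh: bool = False,
):
    """Contour stack -> capped cloud -> Poisson field -> mesh -> clipped mask."""
    params = params or PoissonParams()
    cloud = add_end_caps(stack_to_point_cloud(stack), stack)
    field = reconstruct_field(cloud, params)
    mesh = extract_isosurface(field)
    mask = voxelize(mesh, reference)
    s_lo = float(stack.contours[0].arclength) + clip_margin_mm
    s_hi = float(stack.contours[-1].arclength) - clip_margin_mm
    mask = clip_mask(mask, cl, s_lo, s_hi)
    if return_mesh:
        return mask, mesh
    return mask
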