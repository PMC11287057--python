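"""Aortic root / LVOT centerline extraction.

The centerline is found as a minimal-cost path through a cost image built
from two tube cues: a multiscale Frangi vesselness response and a per-slice
circular Hough response on the gradient edge map.  The path runs between the
LVOT landmark and a point extrapolated beyond the sinuses, is smoothed, and
is resampled at a uniform arclength step with rotation-minimizing frames so
that perpendicular cross-sections can be defined along it.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline
from skimage import filters, transform

from .imaging import ImageVolume, LandmarkSet

__all__ = [
    "ScalarMap",
    "Centerline",
    "vesselness",
    "hough_circle_map",
    "cost_image",
    "dijkstra_path",
    "resample_centerline",
    "compute_centerline",
]

DEFAULT_SCALES_MM = (6.0, 8.0, 10.0, 12.0)
DEFAULT_HOUGH_RANGE_MM = (5.0, 18.0)


class ScalarMap(ImageVolume):
    """Nonnegative scalar field (filter response or path cost) on a grid.

    ``+inf`` is allowed and marks impassable voxels for the path search.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.asarray(self.values)
        if np.any(np.isnan(vals)) or np.any(vals == -np.inf):
            raise ValueError("scalar map must not contain NaN or -inf")


@dataclasses.dataclass
class Centerline:
    """Arclength-parameterized 3D curve with per-point orthonormal frames.

    ``frames[i]`` is a pair of unit vectors (u, v) spanning the plane normal
    to ``tangents[i]``; frames are rotation-minimizing along the curve.
    """

    points: np.ndarray          # (n, 3) world mm
    arclengths: np.ndarray      # (n,) cumulative mm, strictly increasing
    tangents: np.ndarray        # (n, 3) unit
    frames: np.ndarray          # (n, 2, 3) unit (u, v)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.arclengths = np.asarray(self.arclengths, dtype=float)
        self.tangents = np.asarray(self.tangents, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        if np.any(np.diff(self.arclengths) <= 0):
            raise ValueError("arclengths must be strictly increasing")

    @property
    def length(self) -> float:
        return float(self.arclengths[-1] - self.arclengths[0])

    def __len__(self) -> int:
        return len(self.points)

    def frame_at(self, s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(point, tangent, u, v) at arclength ``s``, nearest sample."""
        i = int(np.argmin(np.abs(self.arclengths - s)))
        return self.points[i], self.tangents[i], self.frames[i, 0], self.frames[i, 1]

    def project(self, points: np.ndarray) -> np.ndarray:
        """Arclength of the nearest centerline sample for each world point."""
        from scipy.spatial import cKDTree

        _, idx = cKDTree(self.points).query(np.asarray(points, dtype=float))
        return self.arclengths[idx]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        step = float(np.median(np.diff(self.arclengths))) if len(self) > 1 else 0.0
        with open(path, "w") as fh:
            json.dump({"points": self.points.tolist(), "step_mm": step}, fh)
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "Centerline":
        with open(path) as fh:
            data = json.load(fh)
        step = float(data.get("step_mm") or 1.0)
        return resample_centerline(np.asarray(data["points"], dtype=float), step_mm=step)


# -- tube cues -------------------------------------------------------------


def _require_isotropic(image: ImageVolume) -> float:
    sp = image.spacing
    if not np.allclose(sp, sp[0], rtol=1e-3):
        raise ValueError(
            f"anisotropic spacing {tuple(sp)}; resample to isotropic voxels first"
        )
    return float(sp[0])


def vesselness(image: ImageVolume, scales_mm=DEFAULT_SCALES_MM) -> ScalarMap:
    """Multiscale Frangi tubularity response in [0, 1].

    Bright tubes on a dark background: the response is the per-voxel maximum
    over scales of the Frangi measure built from the Hessian eigenvalues
    (|l1| <= |l2| <= |l3|, requiring l2, l3 < 0), with alpha = beta = 0.5 and
    the structureness scale set to half the maximum Hessian norm.
    """
    scales_mm = np.atleast_1d(np.asarray(scales_mm, dtype=float))
    if scales_mm.size == 0:
        raise ValueError("at least one vesselness scale is required")
    voxel = _require_isotropic(image)
    sigmas = scales_mm / voxel
    resp = filters.frangi(
        np.asarray(image.values, dtype=float),
        sigmas=sigmas,
        alpha=0.5,
        beta=0.5,
        gamma=None,
        black_ridges=False,
    )
    peak = resp.max()
    if peak > 0:
        resp = resp / peak
    return ScalarMap(values=resp, spacing=image.spacing,
                     origin=image.origin, direction=image.direction)


def hough_circle_map(
    image: ImageVolume,
    radius_range_mm=DEFAULT_HOUGH_RANGE_MM,
    axis: int = 2,
) -> ScalarMap:
    """Per-slice circular Hough accumulator, max over radii, in [0, 1].

    Each slice perpendicular to ``axis`` is reduced to a binary edge map
    (gradient magnitude above the Otsu threshold) and voted into circle
    centres for radii spanning ``radius_range_mm``; the map is normalized to
    [0, 1] over the whole volume (constant images yield all zeros).
    """
    r_lo, r_hi = float(radius_range_mm[0]), float(radius_range_mm[1])
    if not (0 < r_lo < r_hi):
        raise ValueError("radius range must be a nonempty positive interval")
    if r_lo < 1.0 or r_hi > 30.0:
        raise ValueError("radius range must lie within [1, 30] mm")
    voxel = _require_isotropic(image)
    radii_px = np.unique(np.round(np.arange(r_lo, r_hi + voxel, voxel) / voxel)).astype(int)
    radii_px = radii_px[radii_px >= 1]

    vol = np.moveaxis(np.asarray(image.values, dtype=float), axis, 0)
    out = np.zeros_like(vol)
    for i, sl in enumerate(vol):
        gmag = filters.sobel(sl)
        if gmag.max() <= 0:
            continue
        edges = gmag > filters.threshold_otsu(gmag)
        if not edges.any():
            continue
        acc = transform.hough_circle(edges, radii_px)
        out[i] = acc.max(axis=0)
    out = np.moveaxis(out, 0, axis)
    peak = out.max()
    if peak > 0:
        out = out / peak
    return ScalarMap(values=out, spacing=image.spacing,
                     origin=image.origin, direction=image.direction)


def cost_image(
    v: ScalarMap,
    h: ScalarMap,
    w_v: float = 0.5,
    w_h: float = 0.5,
    eps: float = 1e-3,
) -> ScalarMap:
    """cost = 1 - (w_v * vesselness + w_h * hough) + eps, elementwise."""
    if not v.same_geometry(h):
        raise ValueError("vesselness and Hough maps must share geometry")
    if not np.isclose(w_v + w_h, 1.0):
        raise ValueError("weights must sum to 1")
    cost = 1.0 - (w_v * np.asarray(v.values) + w_h * np.asarray(h.values)) + eps
    return ScalarMap(values=cost, spacing=v.spacing, origin=v.origin, direction=v.direction)


# -- shortest path ---------------------------------------------------------


def _neighbor_offsets() -> np.ndarray:
    offs = np.array(
        [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
         if (i, j, k) != (0, 0, 0)]
    )
    return offs


def _grid_graph(vals: np.ndarray, spacing: np.ndarray, node_mask: np.ndarray):
    """Directed sparse graph over masked voxels; edge u->v costs vals[v]*|step|."""
    from scipy import sparse

    shape = vals.shape
    node_id = np.full(vals.size, -1, dtype=np.int64)
    flat_nodes = np.flatnonzero(node_mask.ravel())
    node_id[flat_nodes] = np.arange(flat_nodes.size)
    idx = np.asarray(np.unravel_index(flat_nodes, shape)).T
    offs = _neighbor_offsets()
    step_mm = np.linalg.norm(offs * spacing[np.newaxis, :], axis=1)
    rows, cols, data = [], [], []
    vals_flat = vals.ravel()
    strides = np.array([shape[1] * shape[2], shape[2], 1], dtype=np.int64)
    for o, smm in zip(offs, step_mm):
        nb = idx + o
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        nb_f = flat_nodes[ok] + int(o @ strides)
        ok2 = node_id[nb_f] >= 0
        src = node_id[flat_nodes[ok][ok2]]
        dst = node_id[nb_f[ok2]]
        rows.append(src)
        cols.append(dst)
        data.append(vals_flat[nb_f[ok2]] * smm)
    graph = sparse.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(flat_nodes.size, flat_nodes.size),
    )
    return graph, flat_nodes, node_id


def dijkstra_path(
    cost: ScalarMap,
    start_world,
    end_world,
    return_cost: bool = False,
    corridor_quantile: float | None = None,
):
    """Minimal-cost 26-connected voxel path through a cost image.

    A step onto neighbour ``n`` costs ``cost[n] * ||step in mm||``.  With
    ``corridor_quantile`` set, the search is restricted to the connected
    low-cost corridor below that cost quantile that contains both endpoints
    (falling back to the full grid if the corridor does not connect them);
    this keeps the graph small on ROI-sized volumes without changing the
    optimum when the path stays inside the corridor.  Returns the voxel path
    as world points (unsmoothed); with ``return_cost=True`` also the total
    path cost.
    """
    from scipy.ndimage import label
    from scipy.sparse.csgraph import dijkstra as cs_dijkstra

    vals = np.asarray(cost.values, dtype=float)
    shape = vals.shape
    start = np.round(cost.world_to_index(np.asarray(start_world, dtype=float))).astype(int)
    end = np.round(cost.world_to_index(np.asarray(end_world, dtype=float))).astype(int)
    for name, vox in (("start", start), ("end", end)):
        if np.any(vox < 0) or np.any(vox >= shape):
            raise ValueError(f"{name} point {vox.tolist()} is outside the volume")
    if np.isinf(vals[tuple(end)]):
        raise ValueError("end point is unreachable from start (infinite-cost barrier)")

    node_mask = np.isfinite(vals)
    if corridor_quantile is not None:
        thr = np.quantile(vals[np.isfinite(vals)], corridor_quantile)
        corridor = node_mask & (vals <= max(thr, vals[tuple(start)], vals[tuple(end)]))
        corridor[tuple(start)] = corridor[tuple(end)] = True
        labels, _ = label(corridor, structure=np.ones((3, 3, 3), dtype=int))
        if labels[tuple(start)] == labels[tuple(end)]:
            node_mask = labels == labels[tuple(start)]

    graph, flat_nodes, node_id = _grid_graph(vals, cost.spacing, node_mask)
    start_n = int(node_id[np.ravel_multi_index(tuple(start), shape)])
    end_n = int(node_id[np.ravel_multi_index(tuple(end), shape)])
    dist, pred = cs_dijkstra(
        graph, directed=True, indices=start_n, return_predecessors=True
    )
    if not np.isfinite(dist[end_n]):
        raise ValueError("end point is unreachable from start (infinite-cost barrier)")
    path_n = [end_n]
    while path_n[-1] != start_n:
        path_n.append(int(pred[path_n[-1]]))
    path_n.reverse()
    idx = np.asarray(np.unravel_index(flat_nodes[np.asarray(path_n)], shape)).T
    world = cost.index_to_world(idx)
    if return_cost:
        return world, float(dist[end_n])
    return world


# -- resampling and frames -------------------------------------------------


def _double_reflection_frames(points: np.ndarray, tangents: np.ndarray) -> np.ndarray:
    """Rotation-minimizing (u, v) frames by the double-reflection method."""
    n = len(points)
    frames = np.empty((n, 2, 3))
    t0 = tangents[0]
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, t0)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - np.dot(ref, t0) * t0
    u /= np.linalg.norm(u)
    frames[0, 0] = u
    frames[0, 1] = np.cross(t0, u)
    for i in range(n - 1):
        u_i = frames[i, 0]
        t_i, t_n = tangents[i], tangents[i + 1]
        d1 = points[i + 1] - points[i]
        c1 = np.dot(d1, d1)
        if c1 < 1e-14:
            frames[i + 1] = frames[i]
            continue
        u_l = u_i - (2.0 / c1) * np.dot(d1, u_i) * d1
        t_l = t_i - (2.0 / c1) * np.dot(d1, t_i) * d1
        d2 = t_n - t_l
        c2 = np.dot(d2, d2)
        u_n = u_l if c2 < 1e-14 else u_l - (2.0 / c2) * np.dot(d2, u_l) * d2
        u_n = u_n - np.dot(u_n, t_n) * t_n
        u_n /= np.linalg.norm(u_n)
        frames[i + 1, 0] = u_n
        frames[i + 1, 1] = np.cross(t_n, u_n)
    return frames


def resample_centerline(points: np.ndarray, step_mm: float = 1.0) -> Centerline:
    """Fit a cubic spline through ordered points; resample at uniform arclength.

    Tangents come from the spline derivative; in-plane frames are transported
    along the curve with minimal rotation (no twist on planar curves).
    """
    pts = np.asarray(points, dtype=float)
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9
    pts = pts[keep]
    if len(pts) < 2:
        raise ValueError("need at least 2 distinct points to fit a centerline")
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    kind = "cubic" if len(pts) >= 4 else "linear"
    if kind == "cubic":
        spline = CubicSpline(chord, pts, axis=0)
    else:
        from scipy.interpolate import interp1d

        spline = interp1d(chord, pts, axis=0, kind="linear")
    # arclength reparameterization on a fine sampling
    t_fine = np.linspace(0.0, chord[-1], max(4 * len(pts), 400))
    p_fine = spline(t_fine)
    s_fine = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(p_fine, axis=0), axis=1))])
    total = s_fine[-1]
    n_out = max(int(np.floor(total / step_mm)) + 1, 2)
    s_out = np.arange(n_out) * step_mm
    if total - s_out[-1] > 0.25 * step_mm:
        s_out = np.append(s_out, total)
    t_out = np.interp(s_out, s_fine, t_fine)
    out_pts = spline(t_out)
    if kind == "cubic":
        deriv = spline(t_out, 1)
    else:
        deriv = np.gradient(out_pts, t_out, axis=0)
    tangents = deriv / np.linalg.norm(deriv, axis=1, keepdims=True)
    frames = _double_reflection_frames(out_pts, tangents)
    arcl = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(out_pts, axis=0), axis=1))])
    return Centerline(points=out_pts, arclengths=arcl, tangents=tangents, frames=frames)


# -- end-to-end ------------------------------------------------------------


def _snap_to_low_cost(cost: ScalarMap, world: np.ndarray, radius_vox: int = 3) -> np.ndarray:
    vox = np.round(cost.world_to_index(world)).astype(int)
    vox = np.clip(vox, 0, np.asarray(cost.shape) - 1)
    lo = np.maximum(vox - radius_vox, 0)
    hi = np.minimum(vox + radius_vox + 1, cost.shape)
    sub = np.asarray(cost.values)[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    best = np.unravel_index(np.argmin(sub), sub.shape)
    return cost.index_to_world(lo + np.asarray(best))


def _resample_iso(image: ImageVolume, spacing_mm: float) -> ImageVolume:
    """Axis-aligned isotropic resampling (linear), for coarse cost cues."""
    from scipy.ndimage import map_coordinates

    extent = (np.asarray(image.shape) - 1) * image.spacing
    dims = np.maximum(np.round(extent / spacing_mm).astype(int) + 1, 2)
    axes = [np.arange(d) * spacing_mm for d in dims]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    world = np.stack([gx, gy, gz], axis=-1) + image.origin
    idx = image.world_to_index(world.reshape(-1, 3))
    vals = map_coordinates(np.asarray(image.values, dtype=float), idx.T, order=1,
                           mode="nearest").reshape(tuple(dims))
    return ImageVolume(values=vals, spacing=np.full(3, spacing_mm),
                       origin=image.origin, direction=np.eye(3))


def _moving_average(points: np.ndarray, window: int = 5) -> np.ndarray:
    if len(points) <= window:
        return points
    kernel = np.ones(window) / window
    sm = np.vstack([np.convolve(points[:, a], kernel, mode="valid") for a in range(3)]).T
    return np.vstack([points[:1], sm, points[-1:]])


def compute_centerline(
    image: ImageVolume,
    landmarks: LandmarkSet,
    scales_mm=DEFAULT_SCALES_MM,
    hough_range_mm=DEFAULT_HOUGH_RANGE_MM,
    step_mm: float = 1.0,
    cost_spacing_mm: float = 1.3,
    return_cost_map: bool = False,
):
    """Full centerline stage: cues -> cost -> Dijkstra -> smooth/resample.

    The cost cues are computed on a working grid of ``cost_spacing_mm``
    isotropic voxels (the responses vary on the millimetre scale of the
    vessel, so a coarser grid loses no usable precision and keeps the cue
    filters and the path graph fast); the final curve is smoothed and spline
    resampled at ``step_mm``, so its precision is not tied to the working
    grid.  Dijkstra runs from the LVOT landmark to a point extrapolated past
    the sinuses along the LVOT-to-valve axis, by twice the valve-to-ostia
    midpoint distance; both endpoints are snapped to the lowest-cost voxel
    within a small ball (the distal one in a wider ball) to tolerate
    landmark imprecision.  The Hough slicing axis is the volume axis most
    aligned with the LVOT-to-valve direction.
    """
    direction = landmarks["valve"] - landmarks["lvot"]
    axis_align = np.abs(image.direction.T @ direction)
    axis = int(np.argmax(axis_align))
    work = image
    if cost_spacing_mm is not None and cost_spacing_mm > float(np.max(image.spacing)):
        work = _resample_iso(image, cost_spacing_mm)
    v = vesselness(work, scales_mm)
    h = hough_circle_map(work, hough_range_mm, axis=axis)
    cost = cost_image(v, h)
    voxel = float(cost.spacing[0])
    mid = 0.5 * (landmarks["rca"] + landmarks["lca"])
    axis_dir = direction / np.linalg.norm(direction)
    end = landmarks["valve"] + 2.0 * np.linalg.norm(mid - landmarks["valve"]) * axis_dir
    end = np.clip(end, cost.origin, cost.index_to_world(np.asarray(cost.shape) - 1))
    start_w = _snap_to_low_cost(cost, landmarks["lvot"],
                                radius_vox=max(int(round(3.0 / voxel)), 2))
    end_w = _snap_to_low_cost(cost, end, radius_vox=max(int(round(8.0 / voxel)), 3))
    raw = dijkstra_path(cost, start_w, end_w, corridor_quantile=0.25)
    smooth = _moving_average(raw, window=5)
    cl = resample_centerline(smooth, step_mm=step_mm)
    if return_cost_map:
        return cl, cost
    return cl
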