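"""TAVI-planning parameters from a segmentation mask.

The clinically relevant measurements are taken on the valve (annulus) plane
and on a parallel plane 3 mm below it toward the LVOT: maximum and minimum
diameter (length of a chord through the contour's centre of mass) and the
enclosed area.  A diameter-along-centerline profile supports plausibility
review of the whole outflow region.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import label, map_coordinates
from shapely.geometry import Polygon
from skimage import measure

from .centerline import Centerline
from .imaging import BinaryMask

__all__ = [
    "ValvePlane",
    "ValveParameters",
    "plane_contour",
    "diameters",
    "polygon_area",
    "annulus_and_lvot_params",
    "diameter_profile",
]


@dataclasses.dataclass
class ValvePlane:
    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise ValueError("plane normal must be nonzero")
        self.normal = n / nn

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, self.normal)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = ref - np.dot(ref, self.normal) * self.normal
        u /= np.linalg.norm(u)
        return u, np.cross(self.normal, u)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump({"origin": self.origin.tolist(), "normal": self.normal.tolist()}, fh)
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ValvePlane":
        with open(path) as fh:
            d = json.load(fh)
        return cls(origin=np.asarray(d["origin"]), normal=np.asarray(d["normal"]))


@dataclasses.dataclass
class ValveParameters:
    d_max: float
    d_min: float
    area: float
    plane: ValvePlane

    def __post_init__(self) -> None:
        if self.d_min > self.d_max + 1e-9:
            raise ValueError("d_min must not exceed d_max")
        if self.area <= 0:
            raise ValueError("area must be positive")


def plane_contour(
    mask: BinaryMask,
    plane: ValvePlane,
    pixel_mm: float = 0.2,
    window_mm: float = 70.0,
) -> np.ndarray:
    """Outer boundary of the mask's cross-section on an arbitrary plane.

    The mask is resampled on the plane by nearest neighbour, the largest
    foreground component is kept, and its outer boundary is traced as the
    0.5-level iso-contour of the in-plane field, giving a sub-pixel closed
    polygon in plane (u, v) mm coordinates relative to the plane origin.
    """
    u, v = plane.basis()
    n_px = int(round(window_mm / pixel_mm)) + 1
    half = (n_px - 1) / 2.0
    a = (np.arange(n_px) - half) * pixel_mm
    au, av = np.meshgrid(a, a, indexing="ij")
    world = plane.origin + au[..., None] * u + av[..., None] * v
    idx = mask.world_to_index(world.reshape(-1, 3))
    vals = map_coordinates(
        mask.values.astype(float), idx.T, order=0, mode="constant", cval=0.0
    ).reshape(n_px, n_px)
    if vals.max() <= 0:
        raise ValueError("plane does not intersect the mask foreground")
    lab, n_comp = label(vals > 0.5)
    if n_comp > 1:
        sizes = np.bincount(lab.ravel())[1:]
        vals = (lab == (int(np.argmax(sizes)) + 1)).astype(float)
    contours = measure.find_contours(vals, level=0.5)
    if not contours:
        raise ValueError("plane does not intersect the mask foreground")
    poly = max(contours, key=lambda c: abs(Polygon(c).area) if len(c) >= 4 else 0.0)
    # pixel indices -> plane mm (coordinates relative to plane origin)
    return (poly - half) * pixel_mm


def polygon_area(polygon: np.ndarray) -> float:
    """Shoelace area (mm^2) of a simple closed polygon."""
    poly = Polygon(np.asarray(polygon, dtype=float))
    if not poly.is_simple:
        raise ValueError("polygon is self-intersecting")
    return float(abs(poly.area))


def diameters(polygon: np.ndarray, sweep_deg: float = 0.5) -> tuple[float, float]:
    """Max/min chord through the centre of mass of a closed contour.

    For each direction of a ``sweep_deg`` sweep over half the circle, the
    chord length is the span between the boundary crossings of the line
    through the area centroid; ``d_max``/``d_min`` are the extremes over the
    sweep.
    """
    pts = np.asarray(polygon, dtype=float)
    if len(pts) < 8:
        raise ValueError("polygon needs at least 8 vertices")
    shp = Polygon(pts)
    if not shp.is_simple:
        raise ValueError("polygon is self-intersecting")
    cx, cy = shp.centroid.x, shp.centroid.y
    if not shp.contains(shp.centroid):
        raise ValueError("centroid lies outside the polygon (not star-shaped about it)")
    q = pts - (cx, cy)
    q_next = np.roll(q, -1, axis=0)

    thetas = np.deg2rad(np.arange(0.0, 180.0, sweep_deg))
    dirs = np.stack([np.cos(thetas), np.sin(thetas)], axis=1)       # (m, 2)
    perp = np.stack([-np.sin(thetas), np.cos(thetas)], axis=1)
    # signed perpendicular offsets of each vertex for each direction
    s0 = q @ perp.T            # (n, m)
    s1 = q_next @ perp.T
    t0 = q @ dirs.T
    t1 = q_next @ dirs.T
    crossing = (s0 * s1) <= 0
    denom = s0 - s1
    safe = np.where(np.abs(denom) < 1e-15, 1.0, denom)
    frac = np.where(np.abs(denom) < 1e-15, 0.5, s0 / safe)
    t_cross = t0 + frac * (t1 - t0)
    t_masked_hi = np.where(crossing, t_cross, -np.inf)
    t_masked_lo = np.where(crossing, t_cross, np.inf)
    chords = t_masked_hi.max(axis=0) - t_masked_lo.min(axis=0)
    valid = np.isfinite(chords)
    if not valid.any():
        raise ValueError("no chord found through the centroid")
    return float(chords[valid].max()), float(chords[valid].min())


def annulus_and_lvot_params(
    mask: BinaryMask,
    plane: ValvePlane,
    cl: Centerline,
    lvot_offset_mm: float = 3.0,
    pixel_mm: float = 0.2,
) -> tuple[ValveParameters, ValveParameters]:
    """Valve parameters at the annulus plane and ``lvot_offset_mm`` below it.

    "Below" means toward the ventricle: the plane normal is oriented along
    increasing centerline arclength (the LVOT is the centerline start), and
    the LVOT plane is shifted against that direction.
    """
    s_plane = float(cl.project(plane.origin[None, :])[0])
    _, tangent, _, _ = cl.frame_at(s_plane)
    normal = plane.normal if np.dot(plane.normal, tangent) >= 0 else -plane.normal
    oriented = ValvePlane(origin=plane.origin, normal=normal)
    lvot_plane = ValvePlane(origin=plane.origin - lvot_offset_mm * normal, normal=normal)

    out = []
    for pl in (oriented, lvot_plane):
        poly = plane_contour(mask, pl, pixel_mm=pixel_mm)
        d_max, d_min = diameters(poly)
        out.append(ValveParameters(d_max=d_max, d_min=d_min,
                                   area=polygon_area(poly), plane=pl))
    return out[0], out[1]


def diameter_profile(
    mask: BinaryMask,
    cl: Centerline,
    step_mm: float = 1.0,
    pixel_mm: float = 0.3,
) -> pd.DataFrame:
    """d_max, d_min and area on perpendicular sections along the centerline.

    Rows where the section misses the mask foreground are flagged absent
    (NaN measurements) rather than raising.
    """
    rows = []
    for s in np.arange(0.0, cl.arclengths[-1] + 1e-9, step_mm):
        origin, tangent, _, _ = cl.frame_at(float(s))
        try:
            poly = plane_contour(mask, ValvePlane(origin=origin, normal=tangent),
                                 pixel_mm=pixel_mm)
            d_max, d_min = diameters(poly)
            rows.append(dict(arclength_mm=float(s), d_max_mm=d_max, d_min_mm=d_min,
                             area_mm2=polygon_area(poly), absent=False))
        except ValueError:
            rows.append(dict(arclength_mm=float(s), d_max_mm=np.nan, d_min_mm=np.nan,
                             area_mm2=np.nan, absent=True))
    return pd.DataFrame(rows)
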