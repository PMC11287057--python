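"""Cross-section resampling, ray-cast contour initialization, and the
oriented point cloud fed to the surface reconstruction.

Cross-sections are multiplanar reconstructions perpendicular to the
centerline at a fixed arclength offset (1 mm by default).  On each section,
the lumen boundary is found by casting equiangular rays outward from the
centerline point and locating, along each intensity profile, the first
radius where the intensity falls below the lumen/background midpoint at an
inward gradient peak.  A periodic spline through the accepted boundary
points yields a closed contour; contours are represented in polar form about
the centerline point (star-convex by construction).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import map_coordinates

from .centerline import Centerline
from .imaging import ImageVolume

log = logging.getLogger(__name__)

__all__ = [
    "CrossSection",
    "Contour",
    "ContourStack",
    "OrientedPointCloud",
    "sample_cross_sections",
    "raycast_boundary",
    "interpolate_contour",
    "stack_to_point_cloud",
    "subsample_stack",
    "build_contour_stack",
]


@dataclasses.dataclass
class CrossSection:
    """A planar reformation perpendicular to the centerline."""

    origin: np.ndarray      # centerline point, world mm
    normal: np.ndarray      # unit tangent
    u: np.ndarray           # in-plane unit axes
    v: np.ndarray
    image2d: np.ndarray     # square patch sampled on the plane
    pixel_mm: float
    arclength: float

    def plane_to_world(self, pts2d: np.ndarray) -> np.ndarray:
        pts2d = np.asarray(pts2d, dtype=float)
        return self.origin + pts2d[..., :1] * self.u + pts2d[..., 1:2] * self.v

    def sample_profile(self, theta: float, radii_mm: np.ndarray) -> np.ndarray:
        """Bilinear intensity profile along the ray at angle ``theta``."""
        n = self.image2d.shape[0]
        c = (n - 1) / 2.0
        d = np.array([np.cos(theta), np.sin(theta)])
        px = c + radii_mm[:, None] * d[None, :] / self.pixel_mm
        return map_coordinates(self.image2d, px.T, order=1, mode="nearest")


@dataclasses.dataclass
class Contour:
    """Closed lumen boundary on one cross-section.

    ``points2d`` are (u, v) mm offsets from the section origin; ``normals3d``
    are outward in-plane unit normals (each has positive dot product with
    the vector from the section origin to the point).
    """

    section: CrossSection
    points2d: np.ndarray
    points3d: np.ndarray
    normals3d: np.ndarray

    def __post_init__(self) -> None:
        nrm = np.linalg.norm(self.normals3d, axis=1)
        if not np.allclose(nrm, 1.0, atol=1e-6):
            raise ValueError("contour normals must be unit length")
        outward = np.einsum("ij,ij->i", self.normals3d, self.points3d - self.section.origin)
        if np.any(outward <= 0):
            raise ValueError("contour normals must point outward")

    @property
    def arclength(self) -> float:
        return self.section.arclength


@dataclasses.dataclass
class ContourStack:
    contours: list[Contour]
    offset_mm: float

    def __post_init__(self) -> None:
        s = np.array([c.arclength for c in self.contours])
        if len(s) > 1 and np.any(np.diff(s) <= 0):
            raise ValueError("contours must be strictly ordered by arclength")

    def __len__(self) -> int:
        return len(self.contours)

    @property
    def arclengths(self) -> np.ndarray:
        return np.array([c.arclength for c in self.contours])

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "offset_mm": self.offset_mm,
            "contours": [
                {
                    "arclength_mm": c.arclength,
                    "origin": c.section.origin.tolist(),
                    "normal": c.section.normal.tolist(),
                    "u": c.section.u.tolist(),
                    "v": c.section.v.tolist(),
                    "points2d": c.points2d.tolist(),
                }
                for c in self.contours
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ContourStack":
        with open(path) as fh:
            data = json.load(fh)
        contours = []
        for c in data["contours"]:
            sec = CrossSection(
                origin=np.asarray(c["origin"], dtype=float),
                normal=np.asarray(c["normal"], dtype=float),
                u=np.asarray(c["u"], dtype=float),
                v=np.asarray(c["v"], dtype=float),
                image2d=np.zeros((2, 2)),
                pixel_mm=1.0,
                arclength=float(c["arclength_mm"]),
            )
            contours.append(_contour_from_points2d(sec, np.asarray(c["points2d"], dtype=float)))
        return cls(contours=contours, offset_mm=float(data["offset_mm"]))


@dataclasses.dataclass
class OrientedPointCloud:
    points: np.ndarray
    normals: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        if self.points.shape != self.normals.shape:
            raise ValueError("points and normals counts must match")
        if not np.allclose(np.linalg.norm(self.normals, axis=1), 1.0, atol=1e-6):
            raise ValueError("normals must be unit vectors")


# -- operations ------------------------------------------------------------


def sample_cross_sections(
    image: ImageVolume,
    cl: Centerline,
    offset_mm: float = 1.0,
    size_mm: float = 60.0,
    pixel_mm: float = 0.3,
    fill: float | None = None,
) -> list[CrossSection]:
    """One multiplanar reformation per ``offset_mm`` of arclength."""
    if fill is None:
        fill = float(np.min(image.values))
    n_px = int(round(size_mm / pixel_mm)) + 1
    half = (n_px - 1) / 2.0
    a = (np.arange(n_px) - half) * pixel_mm
    au, av = np.meshgrid(a, a, indexing="ij")

    sections: list[CrossSection] = []
    targets = np.arange(0.0, cl.arclengths[-1] + 1e-9, offset_mm)
    for s in targets:
        origin, tangent, u, v = cl.frame_at(s)
        world = origin + au[..., None] * u + av[..., None] * v
        img2d = image.sample(world, order=1, fill=fill)
        sections.append(CrossSection(
            origin=origin, normal=tangent, u=u, v=v,
            image2d=img2d, pixel_mm=pixel_mm, arclength=float(s),
        ))
    return sections


def raycast_boundary(
    section: CrossSection,
    n_rays: int = 36,
    r_max_mm: float = 25.0,
    max_median_deviation: float = 0.40,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boundary candidates along equiangular rays from the centerline point.

    Returns ``(thetas, radii_mm, accepted)``.  For each ray, the intensity
    profile is sampled at ``pixel_mm`` steps out to ``r_max_mm``; the
    boundary candidate is the first radius where the intensity crosses below
    the midpoint of the local lumen and background estimates near an inward
    gradient peak (sub-pixel by linear interpolation of the crossing).  Rays
    whose radius deviates more than ``max_median_deviation`` from the median
    of all rays are rejected as implausible; if fewer than half the rays are
    accepted the section is deemed unreliable.
    """
    step = section.pixel_mm
    radii = np.arange(0.0, r_max_mm + step / 2, step)
    thetas = np.arange(n_rays) * (2 * np.pi / n_rays)

    profiles = np.stack([section.sample_profile(t, radii) for t in thetas])
    lumen = float(np.median(profiles[:, radii < 2.0]))
    n_tail = max(int(0.2 * len(radii)), 1)

    boundary = np.full(n_rays, np.nan)
    for i in range(n_rays):
        prof = profiles[i]
        background = float(np.median(prof[-n_tail:]))
        mid = 0.5 * (lumen + background)
        if lumen - background < 1e-6 * (abs(lumen) + abs(background) + 1.0):
            continue  # no lumen/background contrast on this ray
        grad = np.gradient(prof, step)
        below = prof < mid
        above_before = ~below[:-1] & below[1:]
        cross_idx = np.nonzero(above_before)[0]
        if cross_idx.size == 0:
            continue
        j = int(cross_idx[0])
        # require an inward (negative) gradient peak within 1 mm of the crossing
        w = max(int(round(1.0 / step)), 1)
        lo, hi = max(j - w, 0), min(j + w + 2, len(prof))
        if np.min(grad[lo:hi]) >= 0:
            continue
        frac = (mid - prof[j]) / (prof[j + 1] - prof[j])
        boundary[i] = radii[j] + frac * step

    found = np.isfinite(boundary)
    if not found.any():
        raise ValueError("no reliable contour: no boundary point found on any ray")
    med = float(np.median(boundary[found]))
    accepted = found & (np.abs(boundary - med) <= max_median_deviation * med)
    if accepted.sum() < 0.5 * n_rays:
        raise ValueError(
            f"no reliable contour: only {int(accepted.sum())}/{n_rays} rays accepted"
        )
    return thetas, boundary, accepted


def _contour_from_points2d(section: CrossSection, pts2d: np.ndarray) -> Contour:
    pts3d = section.plane_to_world(pts2d)
    # outward in-plane normal from the polygon tangent (closed polygon)
    nxt = np.roll(pts2d, -1, axis=0)
    prv = np.roll(pts2d, 1, axis=0)
    tang = nxt - prv
    nrm2d = np.stack([tang[:, 1], -tang[:, 0]], axis=1)
    flip = np.einsum("ij,ij->i", nrm2d, pts2d) < 0
    nrm2d[flip] *= -1
    nrm2d /= np.linalg.norm(nrm2d, axis=1, keepdims=True)
    normals3d = nrm2d[:, :1] * section.u + nrm2d[:, 1:2] * section.v
    return Contour(section=section, points2d=pts2d, points3d=pts3d, normals3d=normals3d)


def interpolate_contour(
    section: CrossSection,
    thetas: np.ndarray,
    radii: np.ndarray,
    accepted: np.ndarray,
    n_out: int = 72,
) -> Contour:
    """Closed contour via a periodic cubic spline radius(theta).

    The spline passes through the accepted boundary points and fills in the
    rejected rays; the result is resampled at ``n_out`` equiangular
    positions.  Negative interpolated radii indicate an implausible contour
    and raise.
    """
    th = np.asarray(thetas, dtype=float)[accepted]
    r = np.asarray(radii, dtype=float)[accepted]
    if th.size < 6:
        raise ValueError("need at least 6 accepted boundary points")
    th_ext = np.append(th, th[0] + 2 * np.pi)
    r_ext = np.append(r, r[0])
    spline = CubicSpline(th_ext, r_ext, bc_type="periodic")
    th_out = np.arange(n_out) * (2 * np.pi / n_out)
    # evaluate within the periodic domain of the fitted spline
    r_out = spline(th[0] + (th_out - th[0]) % (2 * np.pi))
    if np.any(r_out <= 0):
        raise ValueError("interpolated contour has non-positive radius (implausible)")
    pts2d = np.stack([r_out * np.cos(th_out), r_out * np.sin(th_out)], axis=1)
    return _contour_from_points2d(section, pts2d)


def stack_to_point_cloud(stack: ContourStack) -> OrientedPointCloud:
    """Concatenate all contour points with their outward in-plane normals."""
    if len(stack) == 0:
        raise ValueError("empty contour stack")
    pts = np.concatenate([c.points3d for c in stack.contours])
    nrm = np.concatenate([c.normals3d for c in stack.contours])
    return OrientedPointCloud(points=pts, normals=nrm)


def subsample_stack(stack: ContourStack, offset_mm: float) -> ContourStack:
    """Keep contours at multiples of ``offset_mm``, always keeping the last.

    This mirrors the sparse-annotation scheme: thinning a 1 mm stack to
    2..10 mm while the first and last cross-sections are kept so all stacks
    cover the same centerline range.
    """
    k = offset_mm / stack.offset_mm
    if abs(k - round(k)) > 1e-6 or offset_mm < stack.offset_mm:
        raise ValueError("offset must be an integer multiple of the stack offset")
    k = int(round(k))
    idx = list(range(0, len(stack), k))
    if idx[-1] != len(stack) - 1:
        idx.append(len(stack) - 1)
    return ContourStack(contours=[stack.contours[i] for i in idx], offset_mm=float(offset_mm))


def build_contour_stack(
    image: ImageVolume,
    cl: Centerline,
    offset_mm: float = 1.0,
    size_mm: float = 60.0,
    pixel_mm: float = 0.3,
    n_rays: int = 36,
    n_out: int = 72,
    r_max_mm: float = 25.0,
    edited: dict[float, np.ndarray] | None = None,
) -> ContourStack:
    """Sections -> ray casting -> spline contour for the whole centerline.

    Sections with no reliable contour are skipped (logged).  ``edited`` maps
    arclength (mm) to replacement ``points2d`` arrays, overriding the
    automatic contour at that arclength — the file-based stand-in for the
    expert correction step of the clinical workflow.
    """
    sections = sample_cross_sections(image, cl, offset_mm, size_mm, pixel_mm)
    contours: list[Contour] = []
    skipped = 0
    for sec in sections:
        if edited is not None:
            key = min(edited, key=lambda s: abs(s - sec.arclength), default=None)
            if key is not None and abs(key - sec.arclength) < offset_mm / 2:
                contours.append(_contour_from_points2d(sec, np.asarray(edited[key], dtype=float)))
                continue
        try:
            th, r, acc = raycast_boundary(sec, n_rays=n_rays, r_max_mm=r_max_mm)
            contours.append(interpolate_contour(sec, th, r, acc, n_out=n_out))
        except ValueError as exc:
            skipped += 1
            log.info("section at %.1f mm skipped: %s", sec.arclength, exc)
    if skipped:
        log.warning("%d/%d sections skipped during contour initialization",
                    skipped, len(sections))
    if not contours:
        raise ValueError("no section produced a reliable contour")
    return ContourStack(contours=contours, offset_mm=offset_mm)
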