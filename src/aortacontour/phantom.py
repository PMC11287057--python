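"""Synthetic CT-like aortic-outflow phantoms.

A phantom is a curved tube of varying radius rendered into a voxel grid:
the lumen follows a smooth centerline through user-supplied control points,
and the radius profile is piecewise linear between named anatomical stations
(LVOT, annulus, sinus, sinotubular junction, ascending aorta), with a
sinus-of-Valsalva bulge.  The ground-truth mask is the exact (unblurred)
tube; the image is the tube scaled to CT-like intensities, edge-blurred and
corrupted by additive Gaussian noise.  Landmarks mimic the manual markers
used clinically: LVOT at the centerline start, a valve point at the annulus
station, and coronary ostia offset laterally near the sinus station.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree
from scipy.ndimage import gaussian_filter

from .centerline import Centerline, resample_centerline
from .imaging import BinaryMask, ImageVolume, LandmarkSet

__all__ = ["PhantomSpec", "PhantomOutput", "generate_phantom", "radius_at",
           "default_spec"]

STATION_ORDER = ("lvot", "annulus", "sinus", "stj", "ascending")


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of a synthetic aortic-outflow phantom.

    ``radius_profile`` maps station name -> (arclength mm, radius mm); the
    tube radius is linearly interpolated between stations and held constant
    beyond the first/last station.  Intensities are HU-like (contrast lumen
    ~400, background ~0).  ``edge_softness`` is the Gaussian sigma (mm) of
    the partial-volume blur applied to the ideal binary image before noise.
    """

    centerline_control_points: np.ndarray
    radius_profile: dict[str, tuple[float, float]]
    lumen_intensity: float = 400.0
    background_intensity: float = 0.0
    edge_softness: float = 0.8
    noise_sigma: float = 20.0
    spacing: float = 0.65
    shape: tuple[int, int, int] = (128, 128, 128)
    seed: int = 0

    def __post_init__(self) -> None:
        self.centerline_control_points = np.asarray(
            self.centerline_control_points, dtype=float
        )
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        radii = {k: float(v[1]) for k, v in self.radius_profile.items()}
        if any(r <= 0 for r in radii.values()):
            raise ValueError("all station radii must be positive")
        if "annulus" in radii and "sinus" in radii and radii["sinus"] < radii["annulus"]:
            raise ValueError("sinus radius must be >= annulus radius (bulge)")
        chord = np.linalg.norm(
            np.diff(self.centerline_control_points, axis=0), axis=1
        ).sum()
        if chord <= 20.0:
            raise ValueError("control points must span more than 20 mm of arclength")

    @property
    def stations(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        items = sorted(self.radius_profile.items(), key=lambda kv: kv[1][0])
        s = np.array([v[0] for _, v in items], dtype=float)
        r = np.array([v[1] for _, v in items], dtype=float)
        return s, r, [k for k, _ in items]


@dataclasses.dataclass
class PhantomOutput:
    image: ImageVolume
    truth_mask: BinaryMask
    truth_centerline: Centerline
    landmarks: LandmarkSet
    valve_plane_origin: np.ndarray = None  # convenience: annulus point
    valve_plane_normal: np.ndarray = None


def radius_at(spec: PhantomSpec, s) -> np.ndarray:
    """Tube radius (mm) at arclength ``s`` by piecewise-linear interpolation."""
    stations_s, stations_r, _ = spec.stations
    s = np.asarray(s, dtype=float)
    if np.any(s < stations_s[0] - 1e-9) or np.any(s > _total_arclength(spec) + 1e-9):
        raise ValueError("arclength outside the phantom's range")
    return np.interp(s, stations_s, stations_r)


def _total_arclength(spec: PhantomSpec) -> float:
    cl = resample_centerline(spec.centerline_control_points, step_mm=0.25)
    return float(cl.arclengths[-1])


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Render the phantom image, ground-truth mask, centerline and landmarks.

    The truth mask is resolution-independent: a voxel is foreground when its
    distance to the smoothed centerline (sampled at 0.25 mm) is at most the
    station radius at the nearest centerline sample.  Identical spec + seed
    yields bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    cl = resample_centerline(spec.centerline_control_points, step_mm=0.25)
    total = float(cl.arclengths[-1])
    stations_s, _, names = spec.stations
    if stations_s[-1] > total + 1e-6:
        raise ValueError(
            f"radius profile extends to {stations_s[-1]:.1f} mm but the "
            f"centerline is only {total:.1f} mm long"
        )

    shape = tuple(int(n) for n in spec.shape)
    spacing = np.full(3, float(spec.spacing))
    origin = np.zeros(3)
    # voxel-centre world coordinates (identity orientation)
    axes = [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]
    max_r = max(r for _, r in spec.radius_profile.values())

    world_lo = origin
    world_hi = origin + (np.asarray(shape) - 1) * spacing
    margin = np.interp(cl.arclengths, stations_s, spec.stations[1])
    bad = np.any(
        (cl.points - margin[:, None] < world_lo) |
        (cl.points + margin[:, None] > world_hi),
        axis=1,
    )
    if bad.any():
        s_bad = float(cl.arclengths[np.argmax(bad)])
        raise ValueError(
            f"tube leaves the volume first at arclength {s_bad:.1f} mm; "
            "enlarge the grid or shrink the phantom"
        )

    # distance field evaluated only inside the tube's bounding box
    lo = cl.points.min(axis=0) - max_r - 1.0
    hi = cl.points.max(axis=0) + max_r + 1.0
    sl = tuple(
        slice(
            max(int(np.floor((lo[a] - origin[a]) / spacing[a])), 0),
            min(int(np.ceil((hi[a] - origin[a]) / spacing[a])) + 1, shape[a]),
        )
        for a in range(3)
    )
    gx, gy, gz = np.meshgrid(
        axes[0][sl[0]], axes[1][sl[1]], axes[2][sl[2]], indexing="ij"
    )
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    dist, idx = cKDTree(cl.points).query(pts, workers=-1)
    r_local = np.interp(cl.arclengths[idx], *spec.stations[:2])
    inside = (dist <= r_local).reshape(gx.shape)

    mask = np.zeros(shape, dtype=np.uint8)
    mask[sl] = inside.astype(np.uint8)

    ideal = (
        spec.background_intensity
        + (spec.lumen_intensity - spec.background_intensity) * mask.astype(float)
    )
    if spec.edge_softness > 0:
        ideal = gaussian_filter(ideal, sigma=spec.edge_softness / spec.spacing)
    image_vals = ideal
    if spec.noise_sigma > 0:
        image_vals = image_vals + rng.normal(0.0, spec.noise_sigma, size=shape)

    geom = dict(spacing=spacing, origin=origin, direction=np.eye(3))
    image = ImageVolume(values=image_vals, **geom)
    truth_mask = BinaryMask(values=mask, **geom)

    def point_at(s: float) -> np.ndarray:
        i = int(np.argmin(np.abs(cl.arclengths - s)))
        return cl.points[i]

    s_by_name = dict(zip(names, stations_s))
    s_sinus = s_by_name.get("sinus", total / 2)
    s_annulus = s_by_name.get("annulus", total / 2)
    sinus_pt, sinus_tan, u, v = cl.frame_at(s_sinus)
    r_sinus = float(radius_at(spec, s_sinus))
    landmarks = LandmarkSet(points={
        "lvot": cl.points[0],
        "valve": point_at(s_annulus),
        "rca": sinus_pt + 1.2 * r_sinus * u,
        "lca": sinus_pt + 1.2 * r_sinus * (-0.5 * u + np.sqrt(3) / 2 * v),
    })
    _, ann_tan, _, _ = cl.frame_at(s_annulus)
    return PhantomOutput(
        image=image,
        truth_mask=truth_mask,
        truth_centerline=cl,
        landmarks=landmarks,
        valve_plane_origin=point_at(s_annulus),
        valve_plane_normal=ann_tan,
    )


def default_spec(seed: int = 0, shape: int = 128, spacing: float = 0.65) -> PhantomSpec:
    """A curved aortic-outflow phantom with a sinus bulge.

    Geometry is desk-scale but anatomically proportioned: annulus radius
    12.5 mm (area ~491 mm^2, a typical TAVI annulus), sinus bulge to 16 mm,
    sinotubular junction 13 mm, gently curved centerline of ~55 mm inside a
    128^3 grid at 0.65 mm (the grid must span at least ~83 mm for the tube
    and its end caps to fit).  The seed perturbs the curvature and the
    station radii slightly (sub-mm) so seeded replicates are distinct but
    comparable.
    """
    rng = np.random.default_rng(seed)
    c = shape * spacing / 2  # volume centre, mm
    bend = rng.uniform(4.0, 8.0)
    tilt = rng.uniform(-3.0, 3.0)
    control = np.array([
        [c - 6.0, c - 2.0, c - 27.0],
        [c - 3.0 + tilt * 0.3, c - 1.0, c - 13.0],
        [c, c, c],
        [c + bend * 0.6, c + tilt * 0.4, c + 14.0],
        [c + bend, c + tilt, c + 27.0],
    ])
    jit = lambda lo, hi: float(rng.uniform(lo, hi))  # noqa: E731
    # short plateau around the annulus: a perpendicular cut of a tube whose
    # radius grows at slope m reads r/sqrt(1-m^2), so the plateau keeps the
    # annulus section an exact circle of radius 12.5 mm
    profile = {
        "lvot": (0.0, 10.5 + jit(-0.4, 0.4)),
        "sub_annulus": (15.0, 12.5),
        "annulus": (18.0, 12.5),
        "supra_annulus": (21.0, 12.5),
        "sinus": (30.0, 16.0 + jit(-0.5, 0.5)),
        "stj": (38.0, 13.0 + jit(-0.4, 0.4)),
        "ascending": (50.0, 13.5 + jit(-0.4, 0.4)),
    }
    return PhantomSpec(
        centerline_control_points=control,
        radius_profile=profile,
        spacing=spacing,
        shape=(shape, shape, shape),
        seed=seed,
    )
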