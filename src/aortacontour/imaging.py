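"""Volume and mask data model, world/voxel geometry, NIfTI I/O, ROI crop.

All spatial quantities live in a single world frame: the native (RAS) frame
of the NIfTI affine, in millimetres.  Voxel indices are 0-based and a voxel's
world position is the centre of that voxel.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

log = logging.getLogger(__name__)

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "LandmarkSet",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
    "crop_roi",
]

REQUIRED_LANDMARKS = ("lvot", "rca", "lca", "valve")


@dataclasses.dataclass
class ImageVolume:
    """A 3D scalar grid with world geometry.

    Parameters
    ----------
    values
        3D array of voxel values, indexed ``values[i, j, k]``.
    spacing
        Millimetres per voxel along each index axis (all > 0).
    origin
        World position (mm) of the centre of voxel ``(0, 0, 0)``.
    direction
        3x3 orthonormal matrix; column ``a`` is the world direction of
        index axis ``a``.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive along every axis")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthonormal")

    # -- geometry ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (voxel centres)."""
        aff = np.eye(4)
        aff[:3, :3] = self.direction * self.spacing[np.newaxis, :]
        aff[:3, 3] = self.origin
        return aff

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel indices, shape (..., 3), to world mm."""
        idx = np.asarray(indices, dtype=float)
        return idx * self.spacing @ self.direction.T + self.origin

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points, shape (..., 3), to continuous voxel indices."""
        pts = np.asarray(points, dtype=float)
        return (pts - self.origin) @ self.direction / self.spacing

    def sample(self, points: np.ndarray, order: int = 1, fill: float = 0.0) -> np.ndarray:
        """Interpolate the volume at world points (linear by default)."""
        idx = self.world_to_index(points)
        return map_coordinates(
            np.asarray(self.values, dtype=float),
            idx.reshape(-1, 3).T,
            order=order,
            mode="constant",
            cval=fill,
        ).reshape(np.asarray(points).shape[:-1])

    def same_geometry(self, other: "ImageVolume", atol: float = 1e-5) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )


class BinaryMask(ImageVolume):
    """An ImageVolume whose values are restricted to {0, 1} (uint8)."""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        uniq = np.unique(vals)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        self.values = vals.astype(np.uint8)
        super().__post_init__()

    @property
    def foreground_count(self) -> int:
        return int(self.values.sum())


@dataclasses.dataclass
class LandmarkSet:
    """Named anatomical landmarks in world mm.

    Required roles: ``lvot`` (outflow-tract start), ``rca``/``lca``
    (coronary ostia) and ``valve`` (a point on the annulus plane).
    """

    points: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        pts = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.points.items()}
        for role in REQUIRED_LANDMARKS:
            if role not in pts:
                raise ValueError(f"missing required landmark role: {role!r}")
            if not np.all(np.isfinite(pts[role])):
                raise ValueError(f"landmark {role!r} has non-finite coordinates")
        self.points = pts

    def __getitem__(self, role: str) -> np.ndarray:
        return self.points[role]

    def roi_center(self) -> np.ndarray:
        """Centroid of valve + coronary ostia, the ROI crop centre."""
        return np.mean([self.points["valve"], self.points["rca"], self.points["lca"]], axis=0)


# -- NIfTI I/O -------------------------------------------------------------


def _volume_from_nifti(img: nib.Nifti1Image, as_mask: bool) -> ImageVolume:
    aff = img.affine
    lin = aff[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    direction = lin / spacing[np.newaxis, :]
    values = np.asanyarray(img.dataobj)
    cls = BinaryMask if as_mask else ImageVolume
    if as_mask:
        values = (np.asarray(values) > 0.5).astype(np.uint8)
    return cls(values=values, spacing=spacing, origin=aff[:3, 3], direction=direction)


def read_volume(path: str | Path, as_mask: bool = False) -> ImageVolume:
    """Read a NIfTI volume; geometry is taken from the affine."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - reported with path
        raise ValueError(f"cannot read NIfTI volume {path}: {exc}") from exc
    return _volume_from_nifti(img, as_mask)


def write_volume(vol: ImageVolume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dtype = np.uint8 if isinstance(vol, BinaryMask) else np.float32
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=dtype), vol.affine)
    nib.save(img, str(path))
    return path


def read_landmarks(path: str | Path) -> LandmarkSet:
    import json

    with open(path) as fh:
        data = json.load(fh)
    return LandmarkSet(points={k: np.asarray(v, dtype=float) for k, v in data.items()})


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> Path:
    import json

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({k: list(map(float, v)) for k, v in landmarks.points.items()}, fh, indent=1)
    return path


# -- ROI crop --------------------------------------------------------------


def crop_roi(
    image: ImageVolume,
    landmarks: LandmarkSet,
    side_mm: float = 80.0,
    iso_mm: float = 0.65,
    fill: float | None = None,
) -> ImageVolume:
    """Crop an axis-aligned cubic region of interest around the aortic root.

    The cube of side ``side_mm`` is centred at the centroid of the valve and
    coronary-ostia landmarks and resampled to ``iso_mm`` isotropic voxels
    (linear interpolation for images, nearest for masks).  At the defaults
    (80 mm, 0.65 mm) the output grid is 123 voxels per axis.  Regions falling
    outside the source field of view are filled with the source minimum.
    """
    n = int(round(side_mm / iso_mm))
    center = landmarks.roi_center()
    # axis-aligned world grid, voxel centres, identity orientation
    origin = center - (n - 1) / 2.0 * iso_mm
    axes = np.arange(n) * iso_mm
    gx, gy, gz = np.meshgrid(*(origin[a] + axes for a in range(3)), indexing="ij")
    world = np.stack([gx, gy, gz], axis=-1)

    is_mask = isinstance(image, BinaryMask)
    if fill is None:
        fill = 0.0 if is_mask else float(np.min(image.values))

    idx = image.world_to_index(world.reshape(-1, 3))
    inside = np.all((idx > -0.5) & (idx < np.asarray(image.shape) - 0.5), axis=1)
    if not np.all(inside):
        log.warning(
            "ROI extends outside the source volume: %d/%d voxels filled with %g",
            int((~inside).sum()), idx.shape[0], fill,
        )
    vals = map_coordinates(
        np.asarray(image.values, dtype=float),
        idx.T,
        order=0 if is_mask else 1,
        mode="constant",
        cval=fill,
    ).reshape(n, n, n)

    spacing = np.full(3, iso_mm)
    if is_mask:
        return BinaryMask(values=(vals > 0.5).astype(np.uint8), spacing=spacing,
                          origin=origin, direction=np.eye(3))
    return ImageVolume(values=vals, spacing=spacing, origin=origin, direction=np.eye(3))
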