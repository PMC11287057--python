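"""Segmentation evaluation: overlap and surface metrics, Bland-Altman
agreement, and the contour-offset degradation study.

DSC (Dice similarity coefficient) measures volumetric overlap; ASD (average
surface distance) is the symmetric mean distance between the two boundary
surfaces, sampled at the vertices of their 0.5-level isosurfaces.  The
offset study thins a 1 mm contour stack to 2..10 mm (first and last
cross-sections always kept), reconstructs each thinned stack, and reports
how the mask and the valve parameters degrade relative to the 1 mm mask.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree
from skimage import measure

from .centerline import Centerline
from .contours import ContourStack, subsample_stack
from .imaging import BinaryMask, ImageVolume
from .poisson import PoissonParams, reconstruct_mask
from .quantify import ValvePlane, annulus_and_lvot_params

__all__ = [
    "MetricPair",
    "BlandAltmanResult",
    "OffsetStudyRow",
    "dice",
    "average_surface_distance",
    "per_section_metrics",
    "bland_altman",
    "offset_study",
]


@dataclasses.dataclass
class MetricPair:
    dsc: float
    asd: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.dsc <= 1.0):
            raise ValueError("DSC must lie in [0, 1]")
        if self.asd < 0:
            raise ValueError("ASD must be nonnegative")


@dataclasses.dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pairs: np.ndarray  # (n, 2) of (mean, diff)


@dataclasses.dataclass
class OffsetStudyRow:
    offset_mm: int
    dsc: float
    asd_mm: float
    d_dmax_mm: float
    d_dmin_mm: float
    d_area_mm2: float
    failed: bool = False


def _check_geometry(a: BinaryMask, b: BinaryMask) -> None:
    if not a.same_geometry(b):
        raise ValueError("masks must share grid geometry")


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """2|A∩B| / (|A|+|B|); two empty masks give 1 by convention."""
    _check_geometry(a, b)
    av = a.values > 0
    bv = b.values > 0
    denom = int(av.sum()) + int(bv.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((av & bv).sum()) / denom


def _surface_vertices(mask: BinaryMask) -> np.ndarray:
    vals = np.pad(mask.values.astype(float), 1)
    verts, _, _, _ = measure.marching_cubes(vals, level=0.5)
    return mask.index_to_world(verts - 1.0)


def average_surface_distance(a: BinaryMask, b: BinaryMask) -> float:
    """Symmetric mean vertex-to-nearest-vertex distance (mm) between the
    0.5-isosurfaces of the two masks."""
    _check_geometry(a, b)
    if a.values.max() == 0 or b.values.max() == 0:
        raise ValueError("ASD requires both masks to be nonempty")
    sa = _surface_vertices(a)
    sb = _surface_vertices(b)
    d_ab, _ = cKDTree(sb).query(sa)
    d_ba, _ = cKDTree(sa).query(sb)
    return float((d_ab.sum() + d_ba.sum()) / (len(sa) + len(sb)))


def _plane_sample(mask: BinaryMask, origin, u, v, pixel_mm: float, window_mm: float):
    n_px = int(round(window_mm / pixel_mm)) + 1
    half = (n_px - 1) / 2.0
    a = (np.arange(n_px) - half) * pixel_mm
    au, av = np.meshgrid(a, a, indexing="ij")
    world = origin + au[..., None] * u + av[..., None] * v
    idx = mask.world_to_index(world.reshape(-1, 3))
    return map_coordinates(mask.values.astype(float), idx.T, order=0,
                           mode="constant", cval=0.0).reshape(n_px, n_px)


def per_section_metrics(
    a: BinaryMask,
    b: BinaryMask,
    stack: ContourStack,
    pixel_mm: float = 0.3,
    window_mm: float = 60.0,
) -> tuple[list[MetricPair], int]:
    """2D DSC/ASD on each contour plane; only sections with foreground in
    both masks are scored, the rest are counted as excluded."""
    _check_geometry(a, b)
    results: list[MetricPair] = []
    excluded = 0
    for c in stack.contours:
        sec = c.section
        pa = _plane_sample(a, sec.origin, sec.u, sec.v, pixel_mm, window_mm)
        pb = _plane_sample(b, sec.origin, sec.u, sec.v, pixel_mm, window_mm)
        if pa.max() == 0 or pb.max() == 0:
            excluded += 1
            continue
        inter = np.logical_and(pa > 0.5, pb > 0.5).sum()
        dsc2 = 2.0 * inter / (int((pa > 0.5).sum()) + int((pb > 0.5).sum()))
        ca = measure.find_contours(np.pad(pa, 1), 0.5)
        cb = measure.find_contours(np.pad(pb, 1), 0.5)
        va = np.concatenate(ca) * pixel_mm
        vb = np.concatenate(cb) * pixel_mm
        d_ab, _ = cKDTree(vb).query(va)
        d_ba, _ = cKDTree(va).query(vb)
        asd2 = float((d_ab.sum() + d_ba.sum()) / (len(va) + len(vb)))
        results.append(MetricPair(dsc=float(dsc2), asd=asd2))
    if not results:
        raise ValueError("all sections were excluded (no overlap anywhere)")
    return results, excluded


def bland_altman(x, y) -> BlandAltmanResult:
    """Agreement of paired measurements: diffs are x - y (annotation minus
    prediction, so positive differences mean larger annotated values),
    limits of agreement are mean ± 1.96 SD (SD with n-1 denominator)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    diffs = x - y
    means = 0.5 * (x + y)
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        pairs=np.stack([means, diffs], axis=1),
    )


def offset_study(
    stack1mm: ContourStack,
    params: PoissonParams,
    ref_image: ImageVolume,
    plane: ValvePlane,
    cl: Centerline,
    offsets=range(2, 11),
) -> list[OffsetStudyRow]:
    """Degradation of the reconstructed mask as the contour offset grows.

    The 1 mm mask is the reference; for each offset k the thinned stack
    (first/last contours kept) is reconstructed and compared, reporting DSC,
    ASD, and valve-parameter differences signed as (1 mm value - k mm value).
    Failed reconstructions yield a flagged row and the study continues.
    """
    if abs(stack1mm.offset_mm - 1.0) > 1e-6:
        raise ValueError("offset study requires a 1 mm contour stack")
    m1 = reconstruct_mask(stack1mm, ref_image, cl, params)
    ann1, _ = annulus_and_lvot_params(m1, plane, cl)
    rows: list[OffsetStudyRow] = []
    for k in offsets:
        try:
            stack_k = subsample_stack(stack1mm, float(k))
            mk = reconstruct_mask(stack_k, ref_image, cl, params)
            ann_k, _ = annulus_and_lvot_params(mk, plane, cl)
            rows.append(OffsetStudyRow(
                offset_mm=int(k),
                dsc=dice(m1, mk),
                asd_mm=average_surface_distance(m1, mk),
                d_dmax_mm=ann1.d_max - ann_k.d_max,
                d_dmin_mm=ann1.d_min - ann_k.d_min,
                d_area_mm2=ann1.area - ann_k.area,
            ))
        except (ValueError, RuntimeError):
            rows.append(OffsetStudyRow(offset_mm=int(k), dsc=np.nan, asd_mm=np.nan,
                                       d_dmax_mm=np.nan, d_dmin_mm=np.nan,
                                       d_area_mm2=np.nan, failed=True))
    return rows


def offset_study_frame(rows: list[OffsetStudyRow]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])
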