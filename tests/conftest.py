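"""Shared fixtures: small geometric volumes and cached pipeline runs.

Heavy end-to-end artifacts (seeded curved phantoms pushed through the full
pipeline) are computed once per session and shared across tests.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pytest

from aortacontour.centerline import compute_centerline
from aortacontour.contours import build_contour_stack
from aortacontour.evaluate import average_surface_distance, dice
from aortacontour.imaging import BinaryMask, ImageVolume, crop_roi
from aortacontour.phantom import PhantomSpec, default_spec, generate_phantom
from aortacontour.poisson import PoissonParams, clip_mask, reconstruct_mask
from aortacontour.quantify import ValvePlane, annulus_and_lvot_params

logging.getLogger("aortacontour").setLevel(logging.ERROR)

PIPELINE_SEEDS = (1, 2, 3, 4, 5)


def make_cylinder_mask(radius_mm=10.0, height_mm=40.0, spacing=0.5, pad_mm=4.0):
    """Axis-aligned (z) cylinder mask with known analytic geometry."""
    r_n = int(np.ceil((radius_mm + pad_mm) / spacing))
    h_n = int(np.ceil(height_mm / spacing)) + 1
    n_xy = 2 * r_n + 1
    ax = (np.arange(n_xy) - r_n) * spacing
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    disk = (gx**2 + gy**2) <= radius_mm**2
    vals = np.repeat(disk[:, :, None], h_n, axis=2).astype(np.uint8)
    return BinaryMask(values=vals, spacing=np.full(3, spacing),
                      origin=np.array([-r_n * spacing, -r_n * spacing, 0.0]),
                      direction=np.eye(3))


def straight_tube_spec(radius_mm=10.0, length_mm=40.0, spacing=0.65,
                       noise_sigma=0.0, edge_softness=0.0, seed=0):
    """A straight constant-radius tube phantom spec (axis = z)."""
    n = int(np.ceil((length_mm + 2 * radius_mm + 8) / spacing))
    n_xy = int(np.ceil((2 * radius_mm + 20) / spacing))
    c = n_xy * spacing / 2
    z0 = radius_mm + 3.0
    control = np.array([
        [c, c, z0],
        [c, c, z0 + length_mm / 3],
        [c, c, z0 + 2 * length_mm / 3],
        [c, c, z0 + length_mm],
    ])
    profile = {
        "lvot": (0.0, radius_mm),
        "annulus": (length_mm * 0.4, radius_mm),
        "sinus": (length_mm * 0.6, radius_mm),
        "stj": (length_mm * 0.8, radius_mm),
        "ascending": (length_mm, radius_mm),
    }
    return PhantomSpec(
        centerline_control_points=control,
        radius_profile=profile,
        noise_sigma=noise_sigma,
        edge_softness=edge_softness,
        spacing=spacing,
        shape=(n_xy, n_xy, n),
        seed=seed,
    )


@pytest.fixture(scope="session")
def cylinder_phantom():
    """Noise-free straight tube, radius 10 mm."""
    return generate_phantom(straight_tube_spec())


@pytest.fixture(scope="session")
def soft_cylinder_phantom():
    """Straight tube with realistic edge blur but no noise."""
    return generate_phantom(straight_tube_spec(edge_softness=0.8))


@dataclasses.dataclass
class PipelineResult:
    seed: int
    phantom: object
    roi: ImageVolume
    roi_truth: BinaryMask
    centerline: object
    stack: object
    mask: BinaryMask
    truth_clipped: BinaryMask
    valve_plane: ValvePlane
    annulus: object
    lvot: object
    dsc: float
    asd: float


def run_full_pipeline(seed: int, depth: int = 7) -> PipelineResult:
    ph = generate_phantom(default_spec(seed=seed))
    roi = crop_roi(ph.image, ph.landmarks)
    roi_truth = crop_roi(ph.truth_mask, ph.landmarks)
    cl = compute_centerline(roi, ph.landmarks)
    stack = build_contour_stack(roi, cl)
    mask = reconstruct_mask(stack, roi, cl, PoissonParams(depth=depth))
    vp = ValvePlane(origin=ph.valve_plane_origin, normal=ph.valve_plane_normal)
    ann, lvot = annulus_and_lvot_params(mask, vp, cl)
    truth_c = clip_mask(roi_truth, cl,
                        float(stack.contours[0].arclength) + 0.5,
                        float(stack.contours[-1].arclength) - 0.5)
    return PipelineResult(
        seed=seed, phantom=ph, roi=roi, roi_truth=roi_truth, centerline=cl,
        stack=stack, mask=mask, truth_clipped=truth_c, valve_plane=vp,
        annulus=ann, lvot=lvot, dsc=dice(mask, truth_c),
        asd=average_surface_distance(mask, truth_c),
    )


@pytest.fixture(scope="session")
def pipeline_results():
    """Full pipeline on the five seeded curved phantoms (computed once)."""
    return [run_full_pipeline(seed) for seed in PIPELINE_SEEDS]


@pytest.fixture(scope="session")
def pipeline_result(pipeline_results):
    return pipeline_results[0]
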