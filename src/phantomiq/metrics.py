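"""NEMA NU 2-style image-quality metrics on phantom images.

Implements the hot-sphere segmentation (background-corrected 50%
isocontour), the recovery coefficients (mean / max / peak), percent
background variability (CoV), the contrast recovery coefficient (CRC),
the contrast-to-noise ratio (CNR) and the relative count error in the
cold lung insert.  All statistics operate directly on activity
concentration (kBq/mL); in the phantom context SUV is the
measured-to-true concentration ratio, with no body-weight normalisation.

Masks are boolean arrays over the image grid; voxel indices are 0-based
and world coordinates refer to voxel centres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import Grid3D, PhantomSpec, GeometryError

__all__ = [
    "SegmentationError",
    "PlacementError",
    "SphereResult",
    "BackgroundStats",
    "LungResult",
    "segment_sphere",
    "place_background_vois",
    "recovery_coefficients",
    "contrast_recovery",
    "contrast_noise_ratio",
    "lung_count_error",
    "analyze_image",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class SegmentationError(ValueError):
    """Raised when the isocontour yields no usable component."""


class PlacementError(ValueError):
    """Raised when background VOIs cannot satisfy volume/clearance rules."""


@dataclass
class SphereResult:
    """Per-sphere segmentation mask plus the metric bundle."""

    diameter: float
    mask: np.ndarray
    measured_mean: float
    measured_max: float
    measured_peak: float
    rc_mean: float
    rc_max: float
    rc_peak: float
    crc: float
    cnr: float

    def to_dict(self) -> dict:
        return {
            "diameter_mm": self.diameter,
            "mask_voxels": int(self.mask.sum()),
            "measured_mean_kbq_ml": self.measured_mean,
            "measured_max_kbq_ml": self.measured_max,
            "measured_peak_kbq_ml": self.measured_peak,
            "rc_mean": self.rc_mean,
            "rc_max": self.rc_max,
            "rc_peak": self.rc_peak,
            "crc_percent": self.crc,
            "cnr": self.cnr,
        }


@dataclass
class BackgroundStats:
    """Statistics of the three (or ``n``) uniform background VOIs."""

    voi_masks: list[np.ndarray]
    voi_volumes_ml: list[float]
    mean: float
    sd: float
    cov_per_voi: list[float]
    cov_bg: float


@dataclass
class LungResult:
    """Cold lung-insert VOI and its relative count error."""

    voi_mask: np.ndarray
    relative_count_error: float


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_sphere(
    image: Grid3D,
    center: tuple[float, float, float],
    background_mean: float,
    diameter: float,
    search_margin: float = 5.0,
    background_corrected: bool = True,
) -> np.ndarray:
    """Background-corrected 50% isocontour mask of one hot sphere.

    The local maximum ``S_max`` is searched within a ball of radius
    ``diameter/2 + search_margin`` around the nominal centre (the margin
    prevents locking onto a neighbouring sphere).  The threshold is

        T = B + 0.5 * (S_max - B)

    with ``B`` the background mean (or plain ``0.5 * S_max`` when
    ``background_corrected=False``), and the returned mask is the
    26-connected component of ``{value >= T}`` containing the voxel
    nearest the centre (falling back to the local-maximum voxel).

    Raises
    ------
    SegmentationError
        If no voxel in the search ball rises above the background, i.e.
        there is no sphere to segment.
    """
    d2 = image.distance2_field(center)
    r_search = diameter / 2.0 + search_margin
    ball = d2 <= r_search * r_search
    if not ball.any():
        raise GeometryError("search ball contains no voxel centres")
    smax = float(image.values[ball].max())
    if smax <= background_mean * (1.0 + 1e-9) + 1e-12:
        raise SegmentationError(
            f"no suprathreshold structure near {center}: local max {smax:.4g} "
            f"does not exceed background {background_mean:.4g}"
        )
    if background_corrected:
        thr = background_mean + 0.5 * (smax - background_mean)
    else:
        thr = 0.5 * smax
    labels, _ = ndimage.label(image.values >= thr, structure=_STRUCT26)
    seed = image.nearest_index(center)
    lab = labels[seed]
    if lab == 0:
        # nominal centre below threshold (e.g. off-centre sphere): use argmax
        masked = np.where(ball, image.values, -np.inf)
        lab = labels[np.unravel_index(int(np.argmax(masked)), labels.shape)]
    if lab == 0:
        raise SegmentationError(f"empty isocontour component near {center}")
    return labels == lab


# ---------------------------------------------------------------------------
# background VOIs
# ---------------------------------------------------------------------------


def place_background_vois(
    image: Grid3D,
    spec: PhantomSpec,
    n: int = 3,
    min_volume_ml: float = 61.0,
    voi_radius: float = 20.0,
    voi_height: float = 50.0,
    clearance: float = 15.0,
    ring_radius: float = 70.0,
    axial_offset: float = 60.0,
) -> BackgroundStats:
    """Deterministically place ``n`` cylindrical VOIs in the background.

    The cylinders (radius x height defaults give 62.8 mL >= 61 mL) stand
    parallel to the phantom axis at ``ring_radius`` from the centre, at
    fixed angles 30 + 360 k / n degrees, axially shifted by
    ``axial_offset`` from the sphere plane so that every VOI keeps
    ``clearance`` mm from sphere walls, the lung insert and the body
    outline.  Placement is purely a function of the arguments, so
    repeated calls yield identical masks.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    # geometric clearance checks (independent of the voxel grid)
    max_r_out = max(spec.sphere_diameters) / 2.0 + spec.wall_thickness
    z_low = axial_offset - voi_height / 2.0
    if z_low - max_r_out < clearance:
        raise PlacementError(
            f"axial gap {z_low - max_r_out:.1f} mm to sphere walls below the "
            f"required {clearance} mm clearance"
        )
    if spec.lung_insert is not None:
        gap = ring_radius - voi_radius - spec.lung_insert.diameter / 2.0
        if gap < clearance:
            raise PlacementError(f"lung-insert gap {gap:.1f} mm below clearance")
    angles = [math.radians(30.0 + 360.0 * k / n) for k in range(n)]
    centers = [(ring_radius * math.cos(a), ring_radius * math.sin(a)) for a in angles]
    for cx, cy in centers:
        if spec.body.boundary_distance(cx, cy) - voi_radius < clearance:
            raise PlacementError(
                f"VOI at ({cx:.0f}, {cy:.0f}) too close to the body outline"
            )
    if axial_offset + voi_height / 2.0 > spec.body.length / 2.0:
        raise PlacementError("VOI extends past the axial end of the phantom")

    x = image.axis_coords(0)
    y = image.axis_coords(1)
    z = image.axis_coords(2)
    in_band = np.abs(z - axial_offset) <= voi_height / 2.0
    masks: list[np.ndarray] = []
    vols: list[float] = []
    for cx, cy in centers:
        disk = ((x - cx)[:, None] ** 2 + (y - cy)[None, :] ** 2) <= voi_radius**2
        mask = disk[:, :, None] & in_band[None, None, :]
        vol = float(mask.sum()) * image.voxel_volume_ml
        if vol < min_volume_ml:
            raise PlacementError(
                f"VOI volume {vol:.1f} mL < {min_volume_ml} mL (grid too small?)"
            )
        masks.append(mask)
        vols.append(vol)

    covs = []
    means = []
    for mask in masks:
        v = image.values[mask]
        mu = float(v.mean())
        sd = float(v.std(ddof=1))
        means.append(mu)
        covs.append(sd / mu if mu != 0 else math.inf)
    union = np.zeros_like(masks[0])
    for mask in masks:
        union |= mask
    pooled = image.values[union]
    return BackgroundStats(
        voi_masks=masks,
        voi_volumes_ml=vols,
        mean=float(pooled.mean()),
        sd=float(pooled.std(ddof=1)),
        cov_per_voi=covs,
        cov_bg=float(np.mean(covs)),
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def recovery_coefficients(
    image: Grid3D,
    mask: np.ndarray,
    true_activity: float,
    peak_diameter: float = 12.0,
) -> tuple[float, float, float]:
    """Mean, maximum and peak recovery coefficients of one sphere VOI.

    ``rc_mean``/``rc_max`` divide the VOI mean/maximum by the true filled
    concentration.  ``rc_peak`` uses the mean over a 12-mm-diameter ball
    centred on the hottest voxel, restricted to voxels inside the
    isocontour mask.
    """
    if true_activity <= 0:
        raise ValueError("true_activity must be > 0")
    if not mask.any():
        raise ValueError("mask is empty")
    vals = image.values
    masked = np.where(mask, vals, -np.inf)
    argmax = np.unravel_index(int(np.argmax(masked)), vals.shape)
    peak_center = tuple(
        image.origin[ax] + image.spacing[ax] * argmax[ax] for ax in range(3)
    )
    ball = image.distance2_field(peak_center) <= (peak_diameter / 2.0) ** 2
    peak_region = ball & mask  # argmax voxel is always included
    rc_mean = float(vals[mask].mean()) / true_activity
    rc_max = float(vals[argmax]) / true_activity
    rc_peak = float(vals[peak_region].mean()) / true_activity
    return rc_mean, rc_max, rc_peak


def contrast_recovery(
    sphere_mean: float, bg_mean: float, true_sphere: float, true_bg: float
) -> float:
    """Hot-sphere contrast recovery coefficient (percent).

    CRC = 100 * (measured ratio - 1) / (true ratio - 1), the NEMA
    NU 2-2018 hot-sphere percent contrast.
    """
    if not (true_sphere > true_bg > 0):
        raise ValueError("requires true_sphere > true_bg > 0")
    if bg_mean <= 0:
        raise ValueError("bg_mean must be > 0")
    true_ratio = true_sphere / true_bg
    if true_ratio == 1.0:
        raise ValueError("true contrast ratio of 1 leaves CRC undefined")
    return 100.0 * (sphere_mean / bg_mean - 1.0) / (true_ratio - 1.0)


def contrast_noise_ratio(sphere_mean: float, bg_mean: float, bg_sd: float) -> float:
    """CNR = (sphere mean - background mean) / background SD."""
    if bg_sd <= 0:
        raise ValueError(
            "background SD must be > 0; noiseless images have no defined CNR"
        )
    return (sphere_mean - bg_mean) / bg_sd


def lung_count_error(
    image: Grid3D,
    spec: PhantomSpec,
    bg: BackgroundStats,
    voi_diameter: float = 30.0,
    axial_half_extent: float = 30.0,
) -> LungResult:
    """Relative count error in the cold lung insert (percent).

    Mean over a 30-mm-diameter cylindrical VOI on the insert axis,
    spanning the sphere plane +/- ``axial_half_extent``, divided by the
    background VOI mean.
    """
    if spec.lung_insert is None:
        raise ValueError("phantom spec has no lung insert")
    if bg.mean <= 0:
        raise ValueError("background mean must be > 0")
    cx, cy = spec.lung_insert.center_xy
    x = image.axis_coords(0)
    y = image.axis_coords(1)
    z = image.axis_coords(2)
    if z[0] > -axial_half_extent or z[-1] < axial_half_extent:
        raise GeometryError("lung VOI axial extent exceeds the grid")
    r = voi_diameter / 2.0
    if (
        cx - r < x[0] or cx + r > x[-1] or cy - r < y[0] or cy + r > y[-1]
    ):
        raise GeometryError("lung VOI exits the grid in-plane")
    disk = ((x - cx)[:, None] ** 2 + (y - cy)[None, :] ** 2) <= r * r
    band = np.abs(z) <= axial_half_extent
    mask = disk[:, :, None] & band[None, None, :]
    err = 100.0 * float(image.values[mask].mean()) / bg.mean
    return LungResult(voi_mask=mask, relative_count_error=err)


# ---------------------------------------------------------------------------
# whole-image analysis
# ---------------------------------------------------------------------------


def analyze_image(
    image: Grid3D,
    spec: PhantomSpec,
    background_corrected: bool = True,
) -> tuple[list[SphereResult], BackgroundStats, LungResult]:
    """Run the full metric suite on one phantom image.

    Returns per-sphere results ordered by increasing diameter, the
    background statistics and the lung-insert result.  On a noiseless
    image the background SD is zero and CNR is reported as NaN.
    """
    bg = place_background_vois(image, spec)
    results: list[SphereResult] = []
    order = sorted(
        range(len(spec.sphere_diameters)), key=lambda i: spec.sphere_diameters[i]
    )
    for i in order:
        diam = spec.sphere_diameters[i]
        center = spec.sphere_centers[i]  # type: ignore[index]
        mask = segment_sphere(
            image, center, bg.mean, diam, background_corrected=background_corrected
        )
        rc_mean, rc_max, rc_peak = recovery_coefficients(
            image, mask, spec.sphere_activity
        )
        mean_meas = rc_mean * spec.sphere_activity
        crc = contrast_recovery(
            mean_meas, bg.mean, spec.sphere_activity, spec.background_activity
        )
        cnr = (
            contrast_noise_ratio(mean_meas, bg.mean, bg.sd)
            if bg.sd > 0
            else float("nan")
        )
        results.append(
            SphereResult(
                diameter=diam,
                mask=mask,
                measured_mean=mean_meas,
                measured_max=rc_max * spec.sphere_activity,
                measured_peak=rc_peak * spec.sphere_activity,
                rc_mean=rc_mean,
                rc_max=rc_max,
                rc_peak=rc_peak,
                crc=crc,
                cnr=cnr,
            )
        )
    lung = lung_count_error(image, spec, bg)
    return results, bg, lung
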