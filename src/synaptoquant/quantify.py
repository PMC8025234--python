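"""Puncta/aggregate detection and per-particle statistics.

Implements the field's standard confocal quantification chain: maximum
projection, background subtraction, manual (or Otsu) thresholding of the
original intensities, Gaussian smoothing for segmentation, prominence-
filtered local maxima with marker-seeded watershed to split touching
particles, and per-particle area / integrated-density statistics computed on
the pre-blur intensities. Field summaries report particle density and summed
integrated density per reference area, optionally as percent of a control
mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation

from .core import CalibratedImage, RegionOfInterest, full_frame_roi


@dataclass
class DetectionConfig:
    """Knobs of the detection pipeline.

    ``threshold`` is the manual lower threshold in AU applied to the
    background-subtracted image; ``None`` falls back to Otsu inside the ROI
    (automatic mode, labeled as such in batch logs). ``maxima_prominence``
    is the minimum height (dynamics) a local maximum of the blurred image
    must rise above its merge saddle to seed a particle.
    """

    projection: str = "max"  # {"max", "none"}
    z_range: Optional[Tuple[int, int]] = None
    background_method: str = "rolling_ball"  # {"rolling_ball", "percentile", "none"}
    background_radius: float = 50.0  # px, rolling ball
    background_percentile: float = 25.0
    blur_sigma: float = 0.5  # px
    threshold: Optional[float] = None  # AU; None => Otsu
    maxima_prominence: float = 40.0  # AU
    min_particle_area: int = 5  # px^2

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.projection not in ("max", "none"):
            raise ValueError("projection must be 'max' or 'none'")
        if self.background_method not in ("rolling_ball", "percentile", "none"):
            raise ValueError(f"unknown background_method {self.background_method!r}")


@dataclass
class ParticleTable:
    """Per-particle records plus field-level summary slots."""

    particles: pd.DataFrame
    reference_area_um2: Optional[float] = None
    pixel_size: float = 1.0
    labels: Optional[np.ndarray] = None  # label image, for downstream masking

    @property
    def n_particles(self) -> int:
        return len(self.particles)


def project_stack(
    stack: CalibratedImage, z_range: Optional[Tuple[int, int]] = None
) -> CalibratedImage:
    """Maximum-intensity projection over the selected z slices.

    ``z_range`` is a half-open (start, stop) slice index range; ``None``
    selects all slices. Calibration and channel labels are preserved.
    """
    if "Z" not in stack.axes:
        return stack
    zax = stack.axis("Z")
    nz = stack.data.shape[zax]
    if z_range is None:
        z0, z1 = 0, nz
    else:
        z0, z1 = z_range
    if not (0 <= z0 < z1 <= nz):
        raise ValueError(f"empty or out-of-range z_range {z_range} for {nz} slices")
    sub = np.take(stack.data, np.arange(z0, z1), axis=zax)
    proj = sub.max(axis=zax)
    return CalibratedImage(
        proj, stack.calibration, stack.axes.replace("Z", ""), stack.channel_names
    )


def subtract_background(img: np.ndarray, cfg: DetectionConfig) -> np.ndarray:
    """Background-subtract a 2D image per the configured method."""
    if cfg.background_method == "none":
        return img.copy()
    if cfg.background_method == "percentile":
        return img - np.percentile(img, cfg.background_percentile)
    from skimage.restoration import rolling_ball

    bg = rolling_ball(img, radius=cfg.background_radius)
    return img - bg


def find_maxima(
    img: np.ndarray, prominence: float, mask: Optional[np.ndarray] = None
) -> np.ndarray:
    """Regional maxima whose dynamics (height above merge saddle) >= prominence.

    Returns a boolean marker image with one connected marker per accepted
    maximum plateau. Equivalent to the h-maxima transform: a maximum
    survives iff it cannot be reached from a higher peak without descending
    by at least ``prominence``.
    """
    if prominence <= 0:
        markers = morphology.local_maxima(img)
    else:
        h = morphology.h_maxima(img, prominence)
        markers = h > 0
    if mask is not None:
        markers &= mask
    return markers


def segment_particles(
    img: CalibratedImage,
    roi: Optional[RegionOfInterest] = None,
    cfg: Optional[DetectionConfig] = None,
) -> ParticleTable:
    """Detect particles inside a ROI and tabulate per-particle statistics.

    Pipeline order (fixed): restrict to ROI -> background subtraction ->
    threshold mask on the original (pre-blur) intensities -> Gaussian blur
    -> prominence-filtered maxima inside the mask -> marker-seeded watershed
    splitting touching particles -> statistics on the background-subtracted,
    pre-blur intensities. Fragments below ``min_particle_area`` are dropped.
    An image with no above-threshold pixel yields an empty table.
    """
    cfg = cfg or DetectionConfig()
    work = img
    if "Z" in work.axes and cfg.projection == "max":
        work = project_stack(work, cfg.z_range)
    if work.data.ndim != 2:
        raise ValueError("segment_particles expects a single-channel 2D image")
    data = work.data
    if roi is None:
        roi = full_frame_roi(data.shape)
    roi_mask = roi.to_mask(data.shape)

    bgsub = subtract_background(data, cfg)
    inroi = np.where(roi_mask, bgsub, 0.0)

    thr = cfg.threshold
    if thr is None:
        vals = bgsub[roi_mask]
        thr = float(filters.threshold_otsu(vals)) if vals.size else 0.0
    mask = (bgsub > thr) & roi_mask
    if not mask.any():
        return _empty_table(work)

    blurred = (
        ndimage.gaussian_filter(inroi, cfg.blur_sigma) if cfg.blur_sigma > 0 else inroi
    )
    markers_bool = find_maxima(blurred, cfg.maxima_prominence, mask)
    # 8-connectivity matches the full-connectivity plateaus of the h-maxima
    markers, n_markers = ndimage.label(markers_bool, structure=np.ones((3, 3)))
    if n_markers == 0:
        return _empty_table(work)
    labels = segmentation.watershed(-blurred, markers=markers, mask=mask)

    # min-combination of the binary mask with the original image: statistics
    # are computed on pre-blur (background-subtracted) intensities only.
    pxsize = work.calibration.pixel_size
    props = measure.regionprops_table(
        labels,
        intensity_image=bgsub,
        properties=("label", "area", "centroid_weighted", "intensity_mean"),
    )
    area_px = props["area"]
    keep = area_px >= cfg.min_particle_area
    integ = ndimage.sum_labels(bgsub, labels, index=props["label"])
    table = pd.DataFrame(
        {
            "id": props["label"][keep],
            "y_px": props["centroid_weighted-0"][keep],
            "x_px": props["centroid_weighted-1"][keep],
            "x_um": props["centroid_weighted-1"][keep] * pxsize,
            "y_um": props["centroid_weighted-0"][keep] * pxsize,
            "area_px2": area_px[keep],
            "area_um2": area_px[keep] * pxsize**2,
            "integrated_density_au": integ[keep],
            "mean_intensity_au": props["intensity_mean"][keep],
        }
    ).reset_index(drop=True)
    kept_labels = np.where(np.isin(labels, table["id"].to_numpy()), labels, 0)
    return ParticleTable(table, pixel_size=pxsize, labels=kept_labels)


def _empty_table(img: CalibratedImage) -> ParticleTable:
    cols = [
        "id", "y_px", "x_px", "x_um", "y_um",
        "area_px2", "area_um2", "integrated_density_au", "mean_intensity_au",
    ]
    return ParticleTable(
        pd.DataFrame(columns=cols),
        pixel_size=img.calibration.pixel_size,
        labels=np.zeros(img.data.shape, dtype=np.int32),
    )


def summarize_field(
    table: ParticleTable,
    reference_area_um2: float,
    control_mean: Optional[dict] = None,
) -> pd.Series:
    """Field-level summary: density, sum intensity per area, mean particle area.

    ``density = n_particles / reference_area`` exactly;
    ``sum_intensity_per_area = sum(integrated_density) / reference_area``.
    When ``control_mean`` maps summary keys to control-group means, each
    summary is also reported as percent of control (wild-type = 100%).
    """
    if reference_area_um2 <= 0:
        raise ValueError("reference_area must be > 0")
    n = table.n_particles
    total = float(table.particles["integrated_density_au"].sum()) if n else 0.0
    out = {
        "n_particles": float(n),
        "reference_area_um2": reference_area_um2,
        "density_per_um2": n / reference_area_um2,
        "sum_intensity_per_area_au_um2": total / reference_area_um2,
        "mean_particle_area_um2": (
            float(table.particles["area_um2"].mean()) if n else np.nan
        ),
    }
    if control_mean is not None:
        for key, ctrl in control_mean.items():
            if ctrl == 0:
                raise ValueError(f"control mean for {key!r} is zero")
            out[f"{key}_pct_of_control"] = 100.0 * out[key] / ctrl
    return pd.Series(out)


def ring_diameter(area: float) -> float:
    """Equivalent-circle diameter d = 2 sqrt(A / pi) of a ring-shaped punctum.

    ``area`` and the result share units (µm² -> µm)."""
    if np.any(np.asarray(area) < 0):
        raise ValueError("area must be >= 0")
    return 2.0 * np.sqrt(area / np.pi)


def cytoplasmic_intensity(
    img: CalibratedImage,
    bouton_roi: RegionOfInterest,
    blur_sigma: float = 2.0,
    az_threshold: float = 30.0,
) -> pd.Series:
    """Mean intensity inside a bouton excluding bright (active-zone) regions.

    A Gaussian blur (default sigma 2.0 px) is applied for region finding
    only; pixels of the blurred image above ``az_threshold`` (default 30 AU)
    inside the bouton are excluded, and the mean of the *original* image
    over the remaining cytoplasmic pixels is returned together with the
    excluded-area fraction. Raises if the bright regions cover the bouton.
    """
    if img.data.ndim != 2:
        raise ValueError("cytoplasmic_intensity expects a 2D image")
    mask = bouton_roi.to_mask(img.data.shape)
    cleared = np.where(mask, img.data, 0.0)
    blurred = ndimage.gaussian_filter(cleared, blur_sigma)
    az = (blurred > az_threshold) & mask
    cyto = mask & ~az
    if not cyto.any():
        raise ValueError("no cytoplasmic pixels: bright regions cover entire bouton")
    return pd.Series(
        {
            "mean_cytoplasmic_intensity_au": float(img.data[cyto].mean()),
            "excluded_area_fraction": float(az.sum()) / float(mask.sum()),
            "n_pixels_used": float(cyto.sum()),
        }
    )
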