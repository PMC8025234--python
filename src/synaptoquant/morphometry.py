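"""EM-section morphometry: vesicle axis lengths and elongation, stereological
volume fraction (Delesse principle), 3D volume/surface of labeled bodies,
and T-bar annotation geometry.

Inputs are integer label images (2D sections) or label volumes (3D); the
pipeline does not segment raw micrographs. Diameters come from the
moment-equivalent ellipse of each region (robust to pixelation); a Feret
caliper alternative is available. Elongation is defined as
``long / short >= 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from skimage import measure

from .core import RegionOfInterest


@dataclass
class StereologyResult:
    volume_fraction: float
    reference_area: float  # physical units^2
    object_area_sum: float


def fit_shape(
    label_image: np.ndarray,
    pixel_size: float,
    method: str = "moments",
    min_area_px: int = 4,
) -> pd.DataFrame:
    """Axis lengths and elongation per labeled region of a 2D section.

    Per region the moment-equivalent ellipse gives the long/short diameters
    (``method="feret"`` uses Feret calipers instead); elongation =
    long / short. Regions smaller than ``min_area_px`` pixels are rejected.
    Lengths are in the physical unit of ``pixel_size`` (nm for EM).
    """
    label_image = np.asarray(label_image).astype(np.int32)
    if method not in ("moments", "feret"):
        raise ValueError("method must be 'moments' or 'feret'")
    props = measure.regionprops(label_image)
    rows = []
    for p in props:
        if p.area < min_area_px:
            continue
        if method == "moments":
            long_px, short_px = p.axis_major_length, p.axis_minor_length
        else:
            long_px = p.feret_diameter_max
            # minimal Feret via rotating calipers is not exposed; approximate
            # with the minor axis of the moments ellipse
            short_px = p.axis_minor_length
        if short_px <= 0:
            continue
        rows.append(
            {
                "label": p.label,
                "long_diameter": long_px * pixel_size,
                "short_diameter": short_px * pixel_size,
                "elongation": long_px / short_px,
                "area": p.area * pixel_size**2,
            }
        )
    return pd.DataFrame(
        rows, columns=["label", "long_diameter", "short_diameter", "elongation", "area"]
    )


def volume_fraction(
    label_image: np.ndarray,
    region_mask: Optional[np.ndarray] = None,
    pixel_size: float = 1.0,
) -> StereologyResult:
    """Areal fraction of labeled objects within a reference region.

    By the Delesse principle the areal fraction on random planar sections is
    an unbiased estimator of the volume fraction of the labeled phase.
    """
    label_image = np.asarray(label_image)
    if region_mask is None:
        region_mask = np.ones(label_image.shape, dtype=bool)
    region_mask = np.asarray(region_mask, dtype=bool)
    n_region = int(region_mask.sum())
    if n_region == 0:
        raise ValueError("empty reference region")
    n_obj = int(np.count_nonzero(label_image[region_mask]))
    return StereologyResult(
        volume_fraction=n_obj / n_region,
        reference_area=n_region * pixel_size**2,
        object_area_sum=n_obj * pixel_size**2,
    )


def volume_surface_3d(
    label_volume: np.ndarray,
    voxel_size: float,
    smooth_sigma: float = 1.0,
) -> pd.DataFrame:
    """Volume and surface area per label of a 3D label volume.

    Volume is voxel count x voxel volume; surface area comes from a
    marching-cubes isosurface extracted at the 0.5 level of the Gaussian-
    smoothed (sigma ``smooth_sigma`` voxels) binary label — the smoothing
    removes the staircase overestimate of binary isosurfaces. Labels
    touching the volume boundary are flagged ``clipped``. Units follow
    ``voxel_size`` (nm -> nm^3 / nm^2).
    """
    label_volume = np.asarray(label_volume).astype(np.int32)
    if label_volume.ndim != 3:
        raise ValueError("expected a 3D label volume")
    rows = []
    for lab in np.unique(label_volume):
        if lab == 0:
            continue
        binary = label_volume == lab
        nvox = int(binary.sum())
        idx = np.nonzero(binary)
        clipped = any(
            idx[a].min() == 0 or idx[a].max() == label_volume.shape[a] - 1
            for a in range(3)
        )
        # pad so the isosurface closes at the array border
        padded = np.pad(binary, 2).astype(np.float64)
        if smooth_sigma > 0:
            from scipy import ndimage

            padded = ndimage.gaussian_filter(padded, smooth_sigma)
        verts, faces, _, _ = measure.marching_cubes(
            padded, level=0.5, spacing=(voxel_size,) * 3
        )
        surf = float(measure.mesh_surface_area(verts, faces))
        rows.append(
            {
                "label": int(lab),
                "volume": nvox * voxel_size**3,
                "surface_area": surf,
                "clipped": clipped,
            }
        )
    return pd.DataFrame(rows, columns=["label", "volume", "surface_area", "clipped"])


def polyline_length(points: np.ndarray, pixel_size: float) -> float:
    """Physical length of a polyline annotation."""
    pts = np.asarray(points, dtype=np.float64)
    seg = np.diff(pts, axis=0)
    return float(np.sum(np.hypot(seg[:, 0], seg[:, 1]))) * pixel_size


def polygon_area(points: np.ndarray, pixel_size: float) -> float:
    """Shoelace area of a simple polygon annotation, in physical units^2.

    Raises on self-intersecting polygons.
    """
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) < 3:
        raise ValueError("polygon needs >= 3 vertices")
    from shapely.geometry import Polygon

    poly = Polygon(pts)
    if not poly.is_valid:
        raise ValueError("self-intersecting polygon")
    x, y = pts[:, 0], pts[:, 1]
    area_px = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return float(area_px) * pixel_size**2


def tbar_metrics(
    roof_line: RegionOfInterest,
    pedestal_line: RegionOfInterest,
    area_roi: RegionOfInterest,
    pixel_size: float,
) -> pd.Series:
    """T-bar geometry from manual annotations.

    ``roof_line`` spans the furthest extent of the T-bar roof dense
    material, ``pedestal_line`` its height; ``area_roi`` outlines the dense
    material. Lengths in nm, area in nm^2 for nm-calibrated pixels.
    """
    return pd.Series(
        {
            "roof_length": polyline_length(roof_line.points, pixel_size),
            "pedestal_height": polyline_length(pedestal_line.points, pixel_size),
            "tbar_area": polygon_area(area_roi.points, pixel_size),
        }
    )
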