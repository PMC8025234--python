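"""Spatial-segregation statistics for two-channel aggregate fields.

Two constructions are provided:

* line-profile *peak-to-peak distances* between the two channels, binned
  into a frequency histogram (default 0.06 µm bins up to a 1.2 µm cutoff),
  with a chance distribution obtained by circularly shifting the second
  channel horizontally (default 80 px) before re-measuring;
* *center-of-mass distances*: the Euclidean distance between the
  intensity-weighted centroids of the two channels' thresholded ROIs,
  ``d = sqrt((x1 - x2)^2 + (y1 - y2)^2)``, in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import find_peaks

from .core import RegionOfInterest, polyline_coordinates


@dataclass
class DistanceDistribution:
    """Peak-to-peak distances with binned frequencies for data and null."""

    distances_um: np.ndarray
    null_distances_um: np.ndarray
    bin_width: float = 0.06
    cutoff: float = 1.2
    shift_px: int = 80

    def histogram(self) -> pd.DataFrame:
        """Percent frequency per bin for data and shifted-null distances.

        Distances beyond the cutoff are discarded before normalization, so
        each frequency column sums to 100%.
        """
        edges = np.arange(0.0, self.cutoff + self.bin_width / 2, self.bin_width)
        rows = {}
        for name, d in (("data", self.distances_um), ("null", self.null_distances_um)):
            d = np.asarray(d, dtype=np.float64)
            d = d[d <= self.cutoff]
            counts, _ = np.histogram(d, bins=edges)
            freq = 100.0 * counts / counts.sum() if counts.sum() else counts * 0.0
            rows[f"{name}_pct"] = freq
        return pd.DataFrame(
            {"bin_left_um": edges[:-1], "bin_right_um": edges[1:], **rows}
        )


@dataclass
class CenterDistance:
    d: float  # physical units (pixel_unit of the calibration)
    center1: Tuple[float, float]  # (x, y), physical units
    center2: Tuple[float, float]


def line_profile(
    img: np.ndarray,
    line: RegionOfInterest,
    width: int = 1,
    pixel_size: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Intensity profile along a (segmented) line ROI.

    Samples the image by bilinear interpolation at one-pixel arc-length
    steps, averaging ``width`` samples taken perpendicular to the local line
    direction. Returns ``(positions_um, values)``.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    if line.kind not in ("line", "polyline"):
        raise ValueError("line_profile needs a line or polyline ROI")
    coords = polyline_coordinates(line.points, step=1.0)
    if len(coords) < 2:
        raise ValueError("degenerate line")
    # local tangent -> unit normal per sample
    tang = np.gradient(coords, axis=0)
    norm = np.column_stack([-tang[:, 1], tang[:, 0]])
    norm /= np.maximum(np.hypot(norm[:, 0], norm[:, 1])[:, None], 1e-12)
    offsets = np.arange(width) - (width - 1) / 2.0
    acc = np.zeros(len(coords))
    for off in offsets:
        pts = coords + off * norm
        acc += ndimage.map_coordinates(
            np.asarray(img, dtype=np.float64),
            [pts[:, 1], pts[:, 0]],  # (row=y, col=x)
            order=1,
            mode="nearest",
        )
    values = acc / width
    positions = np.arange(len(coords)) * pixel_size
    return positions, values


def _subpixel_peak(positions: np.ndarray, values: np.ndarray, i: int) -> float:
    """Parabolic refinement of peak index i; returns position."""
    if 0 < i < len(values) - 1:
        y0, y1, y2 = values[i - 1], values[i], values[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            step = positions[1] - positions[0]
            return float(positions[i] + np.clip(delta, -0.5, 0.5) * step)
    return float(positions[i])


def peak_to_peak(
    profile1: Tuple[np.ndarray, np.ndarray],
    profile2: Tuple[np.ndarray, np.ndarray],
    min_prominence_frac: float = 0.1,
    min_height: Optional[float] = None,
) -> float:
    """Distance between channel 1's global maximum and channel 2's nearest
    local maximum along a shared line profile (µm).

    Peaks are refined to sub-pixel positions by parabolic interpolation.
    Local maxima of channel 2 must be prominent above
    ``min_prominence_frac`` of that profile's dynamic range and, when
    ``min_height`` is given, rise above that absolute intensity — the
    height floor keeps noise wiggles from being counted as peaks.
    """
    p1, v1 = profile1
    p2, v2 = profile2
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("no peak: flat profile")
    if min_height is not None and v1.max() < min_height:
        raise ValueError("no peak above height floor in channel 1")
    i1 = int(np.argmax(v1))
    pos1 = _subpixel_peak(p1, v1, i1)
    prom = min_prominence_frac * np.ptp(v2)
    idx, _ = find_peaks(v2, prominence=prom)
    # endpoints can be maxima too
    cand = list(idx)
    if v2[0] >= v2[1]:
        cand.append(0)
    if v2[-1] >= v2[-2]:
        cand.append(len(v2) - 1)
    if min_height is not None:
        cand = [i for i in cand if v2[i] >= min_height]
    if not cand:
        raise ValueError("no peak in channel 2")
    pos2 = np.array([_subpixel_peak(p2, v2, i) for i in cand])
    return float(np.min(np.abs(pos2 - pos1)))


def shifted_null(img: np.ndarray, shift_px: int = 80) -> np.ndarray:
    """Circularly shift a channel horizontally (wrap-around) by shift_px.

    Used to build the chance peak-to-peak distribution: the wrap preserves
    the pixel population so data and null histograms are comparable.
    """
    img = np.asarray(img)
    if shift_px >= img.shape[-1]:
        shift_px = shift_px % img.shape[-1]
    return np.roll(img, shift_px, axis=-1)


def peak_distance_distribution(
    ch1: np.ndarray,
    ch2: np.ndarray,
    lines: Sequence[RegionOfInterest],
    pixel_size: float,
    width: int = 3,
    bin_width: float = 0.06,
    cutoff: float = 1.2,
    shift_px: int = 80,
    min_height: Optional[float] = "auto",  # type: ignore[assignment]
) -> DistanceDistribution:
    """Peak-to-peak distances over many lines, with the pixel-shift null.

    ``min_height="auto"`` sets the peak height floor per channel to
    median + 5 * MAD of the whole image, so only genuine puncta count as
    peaks on both the data and the shifted-null measurements.
    """
    def _floor(img: np.ndarray) -> float:
        med = float(np.median(img))
        mad = float(np.median(np.abs(img - med)))
        return med + 5 * 1.4826 * mad

    h2: Optional[float]
    if isinstance(min_height, str) and min_height == "auto":
        h1, h2 = _floor(ch1), _floor(ch2)
    else:
        h1 = h2 = min_height
    null_ch2 = shifted_null(ch2, shift_px)
    data, null = [], []
    for line in lines:
        try:
            prof1 = line_profile(ch1, line, width, pixel_size)
            if h1 is not None and prof1[1].max() < h1:
                continue
        except ValueError:
            continue
        try:
            data.append(
                peak_to_peak(
                    prof1, line_profile(ch2, line, width, pixel_size), min_height=h2
                )
            )
        except ValueError:
            pass
        try:
            null.append(
                peak_to_peak(
                    prof1,
                    line_profile(null_ch2, line, width, pixel_size),
                    min_height=h2,
                )
            )
        except ValueError:
            pass
    return DistanceDistribution(
        np.asarray(data), np.asarray(null), bin_width, cutoff, shift_px
    )


def center_of_mass(
    img: np.ndarray,
    roi_mask: np.ndarray,
    threshold: float = 0.0,
) -> Tuple[float, float]:
    """Intensity-weighted centroid (x, y) in px over a thresholded ROI."""
    img = np.asarray(img, dtype=np.float64)
    sel = roi_mask & (img > threshold)
    weights = np.where(sel, img, 0.0)
    total = weights.sum()
    if total <= 0:
        raise ValueError("zero total intensity in ROI")
    ys, xs = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    return float((xs * weights).sum() / total), float((ys * weights).sum() / total)


def center_distance(
    ch1: np.ndarray,
    ch2: np.ndarray,
    roi1: RegionOfInterest,
    roi2: RegionOfInterest,
    pixel_size: float,
    thr1: float = 0.0,
    thr2: float = 0.0,
) -> CenterDistance:
    """Distance between the two channels' intensity centers of mass.

    Each channel's center is the intensity-weighted centroid over its own
    thresholded ROI; the distance is reported in the physical unit of
    ``pixel_size``.
    """
    m1 = roi1.to_mask(np.asarray(ch1).shape)
    m2 = roi2.to_mask(np.asarray(ch2).shape)
    x1, y1 = center_of_mass(ch1, m1, thr1)
    x2, y2 = center_of_mass(ch2, m2, thr2)
    d = float(np.hypot(x1 - x2, y1 - y2)) * pixel_size
    return CenterDistance(
        d=d,
        center1=(x1 * pixel_size, y1 * pixel_size),
        center2=(x2 * pixel_size, y2 * pixel_size),
    )
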