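"""Colocalization statistics: thresholded Pearson correlation with a
flipped-channel chance control, and binary mask area overlap.

The Pearson coefficient is computed over ROI pixels where either channel
exceeds its threshold (OR rule; the AND rule would inflate r and is
available via ``qualify="and"``). The chance control mirrors the second
channel left-right within the ROI bounding box before recomputing r, so any
residual correlation estimates stochastic overlap at the same spot density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage import filters

from .core import RegionOfInterest


@dataclass
class ColocResult:
    r_data: float
    r_flipped: float
    n_pixels_used: int
    n_pixels_flipped: int
    thr1: float
    thr2: float


class UndefinedCorrelationError(ValueError):
    """Fewer than two qualifying pixels, or zero variance in a channel."""


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2:
        raise UndefinedCorrelationError("fewer than 2 qualifying pixels")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise UndefinedCorrelationError("zero variance over qualifying pixels")
    return float(np.corrcoef(a, b)[0, 1])


def flip_horizontal(img: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    """Mirror an image left-right within the bounding box of a ROI mask."""
    ys, xs = np.nonzero(roi_mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    out = img.copy()
    out[y0:y1, x0:x1] = img[y0:y1, x0:x1][:, ::-1]
    return out


def pearson_above_threshold(
    ch1: np.ndarray,
    ch2: np.ndarray,
    roi: Optional[RegionOfInterest] = None,
    thr1: Optional[float] = None,
    thr2: Optional[float] = None,
    qualify: str = "or",
) -> ColocResult:
    """Thresholded Pearson r of two channels plus the flipped-channel control.

    Thresholds default to per-channel Otsu inside the ROI. Pixels whose
    mirror position falls outside the ROI are excluded from the control.
    """
    ch1 = np.asarray(ch1, dtype=np.float64)
    ch2 = np.asarray(ch2, dtype=np.float64)
    if ch1.shape != ch2.shape:
        raise ValueError("channels must have the same shape")
    if qualify not in ("or", "and"):
        raise ValueError("qualify must be 'or' or 'and'")
    roi_mask = (
        roi.to_mask(ch1.shape) if roi is not None else np.ones(ch1.shape, dtype=bool)
    )
    if thr1 is None:
        thr1 = float(filters.threshold_otsu(ch1[roi_mask]))
    if thr2 is None:
        thr2 = float(filters.threshold_otsu(ch2[roi_mask]))

    def qualifying(b: np.ndarray) -> np.ndarray:
        above = (ch1 > thr1) | (b > thr2) if qualify == "or" else (ch1 > thr1) & (b > thr2)
        return above & roi_mask

    sel = qualifying(ch2)
    r_data = _pearson(ch1[sel], ch2[sel])

    flipped = flip_horizontal(ch2, roi_mask)
    valid = roi_mask & flip_horizontal(roi_mask.astype(float), roi_mask).astype(bool)
    sel_f = qualifying(flipped) & valid
    r_flip = _pearson(ch1[sel_f], flipped[sel_f])
    return ColocResult(
        r_data=r_data,
        r_flipped=r_flip,
        n_pixels_used=int(sel.sum()),
        n_pixels_flipped=int(sel_f.sum()),
        thr1=thr1,
        thr2=thr2,
    )


def area_overlap(mask_a: np.ndarray, mask_b: np.ndarray) -> dict:
    """Overlap fractions of two binary masks, in percent.

    Returns ``a_overlap_pct`` = |A∩B|/|A|, ``b_overlap_pct`` = |A∩B|/|B| and
    ``b_only_pct`` = |B\\A|/|B| (the "only"-positive area left after
    subtracting the copositive area).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must have the same shape")
    na, nb = a.sum(), b.sum()
    if na == 0 or nb == 0:
        raise ValueError("empty mask in denominator")
    inter = np.count_nonzero(a & b)
    return {
        "a_overlap_pct": 100.0 * inter / na,
        "b_overlap_pct": 100.0 * inter / nb,
        "b_only_pct": 100.0 * (nb - inter) / nb,
    }
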