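"""Core data containers shared across the pipeline.

Conventions used everywhere in this package:

* pixel coordinates are 0-based with pixel centers at integer coordinates,
  ordered ``(y, x)`` for arrays and ``(x, y)`` inside ROI point lists
  (matching the common JSON ROI interchange convention);
* physical units are explicit: micrometres for confocal data, nanometres
  for EM, seconds for time, nanoamperes for current;
* image arrays are ``float64`` internally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np


@dataclass
class Calibration:
    """Physical calibration of an image.

    Parameters
    ----------
    pixel_size : float
        Lateral pixel size in µm/px (or nm/px for EM data; the unit is
        carried by ``pixel_unit``).
    frame_interval : float, optional
        Time between frames in seconds, for movies.
    pixel_unit : str
        Unit of ``pixel_size`` ("um" or "nm").
    """

    pixel_size: float
    frame_interval: Optional[float] = None
    pixel_unit: str = "um"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval is not None and self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")


@dataclass
class CalibratedImage:
    """An image (2D, z-stack, multichannel and/or time-lapse) with calibration.

    ``data`` axes are normalized to a subset of ``(T, Z, C, Y, X)``; the
    ``axes`` string records which are present, e.g. ``"YX"``, ``"ZYX"``,
    ``"TCYX"``. Singleton axes are kept explicit so downstream code can
    index by name.
    """

    data: np.ndarray
    calibration: Calibration
    axes: str = "YX"
    channel_names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != len(self.axes):
            raise ValueError(
                f"axes {self.axes!r} do not match array of ndim {self.data.ndim}"
            )
        if not set(self.axes) <= set("TZCYX"):
            raise ValueError(f"unknown axis letters in {self.axes!r}")
        if self.axes[-2:] != "YX":
            raise ValueError("trailing axes must be YX")

    @property
    def shape(self):
        return self.data.shape

    def axis(self, letter: str) -> int:
        """Index of a named axis; raises if absent."""
        return self.axes.index(letter)

    def channel(self, i: int) -> "CalibratedImage":
        """Extract one channel, dropping the C axis."""
        if "C" not in self.axes:
            raise ValueError("image has no channel axis")
        c = self.axis("C")
        data = np.take(self.data, i, axis=c)
        name = None
        if self.channel_names is not None:
            name = [self.channel_names[i]]
        return CalibratedImage(
            data, self.calibration, self.axes.replace("C", ""), name
        )

    def frame(self, t: int) -> "CalibratedImage":
        """Extract one time point, dropping the T axis."""
        if "T" not in self.axes:
            raise ValueError("image has no time axis")
        data = np.take(self.data, t, axis=self.axis("T"))
        return CalibratedImage(
            data, self.calibration, self.axes.replace("T", ""), self.channel_names
        )

    def with_data(self, data: np.ndarray) -> "CalibratedImage":
        return replace(self, data=np.asarray(data, dtype=np.float64))


@dataclass
class RegionOfInterest:
    """A polygon, line, or segmented polyline ROI in pixel coordinates.

    ``points`` is an (n, 2) array of ``(x, y)`` vertices. ``kind`` is one of
    ``"polygon"``, ``"line"`` (2 points), or ``"polyline"``. ``width`` is
    the averaging width in pixels for line-type ROIs.
    """

    kind: str
    points: np.ndarray
    width: float = 1.0
    name: Optional[str] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (x, y)")
        if self.kind not in ("polygon", "line", "polyline"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if self.kind == "polygon" and len(self.points) < 3:
            raise ValueError("polygon needs >= 3 vertices")
        if self.kind in ("line", "polyline") and len(self.points) < 2:
            raise ValueError("line needs >= 2 vertices")
        if self.width < 0:
            raise ValueError("width must be >= 0")

    def to_mask(self, shape) -> np.ndarray:
        """Rasterize a polygon ROI to a boolean mask of the given (Y, X) shape."""
        from skimage.draw import polygon2mask

        if self.kind != "polygon":
            raise ValueError("only polygon ROIs rasterize to masks")
        # polygon2mask expects (row, col) = (y, x)
        mask = polygon2mask(shape, self.points[:, ::-1])
        if not mask.any():
            raise ValueError("ROI rasterizes to an empty mask")
        return mask

    def path_length_px(self) -> float:
        """Total polyline length in pixels."""
        seg = np.diff(self.points, axis=0)
        return float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))

    def to_dict(self) -> dict:
        return {
            "type": self.kind,
            "points": self.points.tolist(),
            "width": self.width,
            "name": self.name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegionOfInterest":
        return cls(
            kind=d["type"],
            points=np.asarray(d["points"], dtype=np.float64),
            width=float(d.get("width", 1.0)),
            name=d.get("name"),
        )


def full_frame_roi(shape) -> RegionOfInterest:
    """Polygon ROI covering an entire (Y, X) frame."""
    h, w = shape[-2], shape[-1]
    pts = [(-0.5, -0.5), (w - 0.5, -0.5), (w - 0.5, h - 0.5), (-0.5, h - 0.5)]
    return RegionOfInterest("polygon", np.asarray(pts), name="full-frame")


def polyline_coordinates(points: np.ndarray, step: float = 1.0) -> np.ndarray:
    """Sample (x, y) coordinates at constant arc-length steps along a polyline.

    Returns an (m, 2) array including both endpoints; ``m = floor(L/step) + 1``.
    """
    pts = np.asarray(points, dtype=np.float64)
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seglen.sum())
    if total <= 0:
        raise ValueError("degenerate (zero-length) polyline")
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    s = np.arange(0.0, total + step * 1e-9, step)
    if s[-1] < total - 1e-9:
        s = np.append(s, total)
    x = np.interp(s, cum, pts[:, 0])
    y = np.interp(s, cum, pts[:, 1])
    return np.column_stack([x, y])
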