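"""File formats: calibrated TIFF images with JSON sidecars, ROI JSON,
trace CSV, and ground-truth CSV/JSON pairs.

Images are multi-page TIFF; the axis order and physical calibration live in
a ``<name>.json`` sidecar next to the TIFF (the TIFF itself stays plain so
any reader can open it). ROIs use a small documented JSON schema:
``{"rois": [{"type": "polygon"|"line"|"polyline", "points": [[x, y], ...],
"width": float, "name": str}]}``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd
import tifffile

from .core import CalibratedImage, Calibration, RegionOfInterest
from .synthdata import GroundTruth

PathLike = Union[str, Path]


class CalibrationError(ValueError):
    """Missing or invalid calibration for an image file."""


def sidecar_path(path: PathLike) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def write_image(path: PathLike, img: CalibratedImage) -> Path:
    """Write a CalibratedImage as TIFF + JSON sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(img.data, dtype=np.float32))
    meta = {
        "axes": img.axes,
        "pixel_size": img.calibration.pixel_size,
        "pixel_unit": img.calibration.pixel_unit,
        "frame_interval_s": img.calibration.frame_interval,
        "channel_names": list(img.channel_names) if img.channel_names else None,
        "shape": list(img.data.shape),
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_image(
    path: PathLike, calibration: Optional[Calibration] = None, axes: Optional[str] = None
) -> CalibratedImage:
    """Read a TIFF into a CalibratedImage.

    Calibration and axes come from the JSON sidecar when present, otherwise
    from the arguments; a missing calibration raises ``CalibrationError``
    naming the missing field. A 2D array without axes info defaults to
    ``"YX"``.
    """
    path = Path(path)
    data = np.asarray(tifffile.imread(path), dtype=np.float64)
    sc = sidecar_path(path)
    channel_names = None
    if sc.exists():
        meta = json.loads(sc.read_text())
        axes = axes or meta.get("axes")
        channel_names = meta.get("channel_names")
        if calibration is None:
            if meta.get("pixel_size") is None:
                raise CalibrationError(f"sidecar {sc} lacks 'pixel_size'")
            calibration = Calibration(
                pixel_size=meta["pixel_size"],
                frame_interval=meta.get("frame_interval_s"),
                pixel_unit=meta.get("pixel_unit", "um"),
            )
    if calibration is None:
        raise CalibrationError(
            f"no calibration for {path}: supply pixel_size via config or sidecar"
        )
    if axes is None:
        if data.ndim == 2:
            axes = "YX"
        else:
            raise CalibrationError(
                f"no axes metadata for {data.ndim}D image {path}; supply axes"
            )
    return CalibratedImage(data, calibration, axes, channel_names)


def write_rois(path: PathLike, rois: List[RegionOfInterest]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({"rois": [r.to_dict() for r in rois]}, indent=2))
    return path


def read_rois(path: PathLike) -> List[RegionOfInterest]:
    d = json.loads(Path(path).read_text())
    return [RegionOfInterest.from_dict(r) for r in d["rois"]]


def write_ground_truth(stem: PathLike, truth: GroundTruth) -> None:
    """Ground truth as CSV records plus a JSON echo of the generator spec."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    truth.records.to_csv(stem.with_suffix(".csv"), index=False)
    stem.with_suffix(".json").write_text(truth.to_json())


def read_trace(path: PathLike) -> pd.DataFrame:
    """Electrophysiology trace CSV with columns time_s, current_nA."""
    df = pd.read_csv(path, comment="#")
    missing = {"time_s", "current_nA"} - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV lacks columns: {sorted(missing)}")
    return df


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping, embedded in output CSVs."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(path: PathLike, table: pd.DataFrame, config: Optional[dict] = None) -> Path:
    """Write a CSV; when a config is given, prefix a '# config_hash:' comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# config_hash: {config_hash(config)}\n")
        table.to_csv(fh, index=False)
    return path
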