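"""Synthetic imaging and electrophysiology data with known ground truth.

Every generator in this module emulates one class of input the quantification
pipeline consumes — diffraction-blurred puncta fields, two-channel fields with
controlled colocalization or inter-channel offset, axonal time-lapse movies,
EM sections of elliptical vesicle profiles, and double-exponential evoked
currents — and returns, next to the data, a :class:`GroundTruth` carrying one
record per generated object plus an echo of the generating spec.

Spots are rendered as analytic Gaussians so the noiseless integrated
intensity of each spot is exactly ``amplitude * 2 * pi * psf_sigma**2``.
Noise is Poisson shot noise on ``signal / poisson_scale`` (rescaled back)
plus additive Gaussian read noise; either component can be switched off.
Identical seeds give bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import CalibratedImage, Calibration

_MAX_PLACEMENT_TRIES = 200


class InfeasibleDensityError(RuntimeError):
    """Raised when spot placement cannot satisfy ``min_separation``."""


@dataclass
class NoiseModel:
    """Shot + read noise. ``poisson_scale`` is the AU per photon-equivalent
    count (0 disables shot noise); ``gaussian_sd`` is additive read noise in AU."""

    poisson_scale: float = 1.0
    gaussian_sd: float = 18.0

    def __post_init__(self) -> None:
        if self.poisson_scale < 0 or self.gaussian_sd < 0:
            raise ValueError("noise parameters must be >= 0")

    @property
    def enabled(self) -> bool:
        return self.poisson_scale > 0 or self.gaussian_sd > 0

    def apply(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = img
        if self.poisson_scale > 0:
            out = rng.poisson(np.clip(out, 0, None) / self.poisson_scale) * float(
                self.poisson_scale
            )
        out = np.asarray(out, dtype=np.float64)
        if self.gaussian_sd > 0:
            out = out + rng.normal(0.0, self.gaussian_sd, size=out.shape)
        return out


NOISE_OFF = NoiseModel(poisson_scale=0.0, gaussian_sd=0.0)


@dataclass
class GroundTruth:
    """Per-object truth records plus an echo of the generating spec."""

    records: pd.DataFrame
    spec: dict

    def to_json(self) -> str:
        return json.dumps(self.spec, indent=2, sort_keys=True)


def _spec_dict(spec) -> dict:
    d = dataclasses.asdict(spec)
    d["__spec__"] = type(spec).__name__
    return d


# ---------------------------------------------------------------------------
# Puncta fields
# ---------------------------------------------------------------------------


@dataclass
class PunctaFieldSpec:
    """Parameters of a 2D field of diffraction-blurred puncta.

    Defaults emulate a confocal acquisition: 0.1 µm pixels, ~100 AU spot
    amplitudes over a 10 AU background, PSF sigma 2 px, and shot + read
    noise giving a peak SNR around 5.
    """

    image_shape: Tuple[int, int] = (256, 256)
    pixel_size: float = 0.1  # µm/px
    n_puncta: int = 100
    amplitude_range: Tuple[float, float] = (80.0, 120.0)
    psf_sigma: float = 2.0  # px
    background: float = 10.0  # AU
    noise: NoiseModel = field(default_factory=NoiseModel)
    min_separation: float = 8.0  # px
    edge_margin: Optional[float] = None  # px; default 3*psf_sigma
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_puncta < 0:
            raise ValueError("n_puncta must be >= 0")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


def _place_points(
    rng: np.random.Generator,
    n: int,
    shape: Tuple[int, int],
    min_separation: float,
    margin: float,
    existing: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Rejection-sample n (x, y) centers keeping min_separation from each
    other and from ``existing``; bounded retries, then InfeasibleDensityError."""
    h, w = shape
    lo = margin
    placed: List[np.ndarray] = [] if existing is None else [np.asarray(existing)]
    pts: List[Tuple[float, float]] = []
    d2 = min_separation**2
    for _ in range(n):
        for attempt in range(_MAX_PLACEMENT_TRIES):
            x = rng.uniform(lo, w - 1 - lo)
            y = rng.uniform(lo, h - 1 - lo)
            ok = True
            for arr in placed:
                if arr.size and np.min((arr[:, 0] - x) ** 2 + (arr[:, 1] - y) ** 2) < d2:
                    ok = False
                    break
            if ok:
                pts.append((x, y))
                placed = [np.asarray(pts)] + (
                    [np.asarray(existing)] if existing is not None else []
                )
                break
        else:
            raise InfeasibleDensityError(
                f"could not place {n} points at min_separation={min_separation} "
                f"in shape {shape} (placed {len(pts)})"
            )
    return np.asarray(pts, dtype=np.float64).reshape(len(pts), 2)


def _render_gaussian_spots(
    shape: Tuple[int, int],
    centers: np.ndarray,
    amplitudes: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Sum of analytic 2D Gaussians evaluated at pixel centers."""
    img = np.zeros(shape, dtype=np.float64)
    if len(centers) == 0:
        return img
    h, w = shape
    r = int(np.ceil(6 * sigma))
    for (x, y), a in zip(centers, amplitudes):
        x0, x1 = max(0, int(np.floor(x)) - r), min(w, int(np.ceil(x)) + r + 1)
        y0, y1 = max(0, int(np.floor(y)) - r), min(h, int(np.ceil(y)) + r + 1)
        xs = np.arange(x0, x1)
        ys = np.arange(y0, y1)[:, None]
        img[y0:y1, x0:x1] += a * np.exp(
            -((xs - x) ** 2 + (ys - y) ** 2) / (2 * sigma**2)
        )
    return img


def generate_puncta_field(
    spec: PunctaFieldSpec,
) -> Tuple[CalibratedImage, GroundTruth]:
    """Generate one noisy puncta field and its ground truth.

    The truth table has one row per spot with pixel and µm centroids, the
    drawn amplitude, the exact noiseless integrated intensity
    ``amplitude * 2 pi psf_sigma^2``, and a ``clipped`` flag for spots whose
    center lies within 3 sigma of the image border.
    """
    rng = np.random.default_rng(spec.seed)
    margin = 3 * spec.psf_sigma if spec.edge_margin is None else spec.edge_margin
    centers = _place_points(
        rng, spec.n_puncta, spec.image_shape, spec.min_separation, margin
    )
    amplitudes = rng.uniform(*spec.amplitude_range, size=spec.n_puncta)
    img = spec.background + _render_gaussian_spots(
        spec.image_shape, centers, amplitudes, spec.psf_sigma
    )
    img = spec.noise.apply(img, rng)

    h, w = spec.image_shape
    m = 3 * spec.psf_sigma
    clipped = (
        (centers[:, 0] < m)
        | (centers[:, 0] > w - 1 - m)
        | (centers[:, 1] < m)
        | (centers[:, 1] > h - 1 - m)
        if len(centers)
        else np.zeros(0, dtype=bool)
    )
    records = pd.DataFrame(
        {
            "x_px": centers[:, 0] if len(centers) else [],
            "y_px": centers[:, 1] if len(centers) else [],
            "x_um": centers[:, 0] * spec.pixel_size if len(centers) else [],
            "y_um": centers[:, 1] * spec.pixel_size if len(centers) else [],
            "amplitude_au": amplitudes,
            "integrated_intensity_au": amplitudes * 2 * np.pi * spec.psf_sigma**2,
            "clipped": clipped,
        }
    )
    image = CalibratedImage(img, Calibration(spec.pixel_size), "YX")
    return image, GroundTruth(records, _spec_dict(spec))


# ---------------------------------------------------------------------------
# Two-channel fields
# ---------------------------------------------------------------------------


@dataclass
class TwoChannelSpec:
    """Two-channel puncta field with controlled colocalization or offset.

    ``mode="shared_fraction"``: that fraction of spots appears at identical
    centroids in both channels (amplitudes drawn independently); remaining
    spots are channel-exclusive. ``mode="center_offset"``: every channel-1
    spot is paired with a channel-2 spot displaced by exactly
    ``center_offset`` µm along ``offset_direction`` degrees.
    """

    base: PunctaFieldSpec = field(default_factory=PunctaFieldSpec)
    mode: str = "shared_fraction"
    shared_fraction: float = 0.5
    center_offset: float = 0.0  # µm
    offset_direction: float = 0.0  # degrees, 0 = +x

    def __post_init__(self) -> None:
        if self.mode not in ("shared_fraction", "center_offset"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        if self.center_offset < 0:
            raise ValueError("center_offset must be >= 0")


def generate_two_channel_field(
    spec: TwoChannelSpec,
) -> Tuple[CalibratedImage, GroundTruth]:
    """Generate a 2-channel field; returns a CYX image and pairing truth."""
    base = spec.base
    rng = np.random.default_rng(base.seed)
    margin = 3 * base.psf_sigma if base.edge_margin is None else base.edge_margin
    offset_px = spec.center_offset / base.pixel_size
    theta = np.deg2rad(spec.offset_direction)
    dvec = offset_px * np.array([np.cos(theta), np.sin(theta)])

    rows = []
    if spec.mode == "shared_fraction":
        n_shared = int(round(spec.shared_fraction * base.n_puncta))
        n_only = base.n_puncta - n_shared
        shared = _place_points(
            rng, n_shared, base.image_shape, base.min_separation, margin
        )
        only1 = _place_points(
            rng, n_only, base.image_shape, base.min_separation, margin, existing=shared
        )
        only2 = _place_points(
            rng,
            n_only,
            base.image_shape,
            base.min_separation,
            margin,
            existing=np.vstack([shared, only1]) if (len(shared) + len(only1)) else None,
        )
        c1 = np.vstack([shared, only1]) if base.n_puncta else np.zeros((0, 2))
        c2 = np.vstack([shared, only2]) if base.n_puncta else np.zeros((0, 2))
        a1 = rng.uniform(*base.amplitude_range, size=len(c1))
        a2 = rng.uniform(*base.amplitude_range, size=len(c2))
        for i in range(len(shared)):
            rows.append((i, "shared", *shared[i], *shared[i]))
        for j in range(len(only1)):
            rows.append((len(shared) + j, "ch1_only", *only1[j], np.nan, np.nan))
        for j in range(len(only2)):
            rows.append((len(shared) + len(only1) + j, "ch2_only",
                         np.nan, np.nan, *only2[j]))
    else:  # center_offset: paired blobs
        # keep pairs min_separation apart from other pairs
        pair_sep = base.min_separation + offset_px
        c1 = _place_points(
            rng, base.n_puncta, base.image_shape, pair_sep, margin + offset_px
        )
        c2 = c1 + dvec
        a1 = rng.uniform(*base.amplitude_range, size=len(c1))
        a2 = rng.uniform(*base.amplitude_range, size=len(c2))
        for i in range(len(c1)):
            rows.append((i, "pair", *c1[i], *c2[i]))

    img1 = base.background + _render_gaussian_spots(
        base.image_shape, c1, a1, base.psf_sigma
    )
    img2 = base.background + _render_gaussian_spots(
        base.image_shape, c2, a2, base.psf_sigma
    )
    img1 = base.noise.apply(img1, rng)
    img2 = base.noise.apply(img2, rng)

    records = pd.DataFrame(
        rows, columns=["pair_id", "role", "x1_px", "y1_px", "x2_px", "y2_px"]
    )
    records["offset_um"] = spec.center_offset if spec.mode == "center_offset" else np.nan
    image = CalibratedImage(
        np.stack([img1, img2]),
        Calibration(base.pixel_size),
        "CYX",
        channel_names=["ch1", "ch2"],
    )
    return image, GroundTruth(records, _spec_dict(spec))


# ---------------------------------------------------------------------------
# Transport movies
# ---------------------------------------------------------------------------


@dataclass
class TransportMovieSpec:
    """Two-channel axon time-lapse with particles moving along a path.

    The path is a polyline in pixel coordinates whose first vertex is the
    proximal end; positive velocities are anterograde (increasing path
    coordinate). ``cotransport_fraction`` of channel-1 particles carry a
    channel-2 signal at the same position in every frame. Defaults emulate
    the study's in vivo acquisitions: 100 nm pixels, 1 s frames.
    """

    n_frames: int = 40
    frame_interval: float = 1.0  # s
    image_shape: Tuple[int, int] = (32, 620)
    pixel_size: float = 0.1  # µm/px
    path: Optional[np.ndarray] = None  # (n,2) (x,y) px; default: horizontal line
    n_particles: int = 3
    velocity_range: Tuple[float, float] = (0.3, 1.2)  # µm/s, signed
    cotransport_fraction: float = 0.5
    pause_prob: float = 0.0
    amplitude_range: Tuple[float, float] = (80.0, 120.0)
    particle_sigma: float = 1.5  # px
    background: float = 10.0
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(1.0, 6.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if not 0.0 <= self.cotransport_fraction <= 1.0:
            raise ValueError("cotransport_fraction must be in [0, 1]")
        if not 0.0 <= self.pause_prob < 1.0:
            raise ValueError("pause_prob must be in [0, 1)")
        if self.path is None:
            h, w = self.image_shape
            self.path = np.array(
                [[2.0, h / 2.0], [w - 3.0, h / 2.0]], dtype=np.float64
            )
        else:
            self.path = np.asarray(self.path, dtype=np.float64)
        if self.path_length_um() < 4.0:
            raise ValueError("path must be at least 4 µm long")

    def path_length_um(self) -> float:
        seg = np.diff(self.path, axis=0)
        return float(np.sum(np.hypot(seg[:, 0], seg[:, 1]))) * self.pixel_size


def _path_xy(path: np.ndarray, s_px: float) -> Tuple[float, float]:
    """(x, y) at arc-length coordinate s (px) along the polyline, clamped."""
    pts = path
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    s = float(np.clip(s_px, 0.0, cum[-1]))
    x = np.interp(s, cum, pts[:, 0])
    y = np.interp(s, cum, pts[:, 1])
    return float(x), float(y)


def generate_transport_movie(
    spec: TransportMovieSpec,
) -> Tuple[CalibratedImage, GroundTruth]:
    """Generate a TCYX movie plus per-particle truth.

    Truth columns: start coordinate (µm along path), velocity (µm/s, signed),
    direction label, cotransport flag, frames visible, and a ``truncated``
    flag set when the particle hit a path end before the movie finished.
    """
    rng = np.random.default_rng(spec.seed)
    L_px = spec.path_length_um() / spec.pixel_size
    n = spec.n_particles

    velocities = rng.uniform(*spec.velocity_range, size=n)
    # Bernoulli per particle so the realized count is binomial, matching how
    # a fraction of cargoes carries the second label in a real axon
    co_flags = rng.random(n) < spec.cotransport_fraction
    amplitudes = rng.uniform(*spec.amplitude_range, size=n)
    co_amplitudes = rng.uniform(*spec.amplitude_range, size=n)

    # start positions: leave room to travel in the drawn direction
    travel_px = np.abs(velocities) * spec.n_frames * spec.frame_interval / spec.pixel_size
    s0 = np.empty(n)
    for i in range(n):
        room = max(L_px - travel_px[i], 0.0)
        start = rng.uniform(0.0, room) if room > 0 else rng.uniform(0.0, L_px)
        s0[i] = start if velocities[i] >= 0 else L_px - start

    # per-frame positions (px along path)
    step_px = velocities * spec.frame_interval / spec.pixel_size
    positions = np.empty((spec.n_frames, n))
    s = s0.copy()
    truncated = np.zeros(n, dtype=bool)
    for t in range(spec.n_frames):
        positions[t] = s
        moving = rng.random(n) >= spec.pause_prob
        s_new = s + np.where(moving, step_px, 0.0)
        hit = (s_new < 0) | (s_new > L_px)
        truncated |= hit
        s = np.clip(s_new, 0.0, L_px)

    frames = np.empty((spec.n_frames, 2) + spec.image_shape, dtype=np.float64)
    for t in range(spec.n_frames):
        xy = np.array([_path_xy(spec.path, positions[t, i]) for i in range(n)])
        ch1 = spec.background + _render_gaussian_spots(
            spec.image_shape, xy, amplitudes, spec.particle_sigma
        )
        co_xy = xy[co_flags] if n else np.zeros((0, 2))
        ch2 = spec.background + _render_gaussian_spots(
            spec.image_shape, co_xy, co_amplitudes[co_flags], spec.particle_sigma
        )
        frames[t, 0] = spec.noise.apply(ch1, rng)
        frames[t, 1] = spec.noise.apply(ch2, rng)

    records = pd.DataFrame(
        {
            "particle": np.arange(n),
            "start_um": s0 * spec.pixel_size,
            "velocity_um_s": velocities,
            "direction": np.where(velocities >= 0, "anterograde", "retrograde"),
            "cotransport": co_flags,
            "frames_visible": spec.n_frames,
            "truncated": truncated,
        }
    )
    image = CalibratedImage(
        frames,
        Calibration(spec.pixel_size, frame_interval=spec.frame_interval),
        "TCYX",
        channel_names=["cargo", "co"],
    )
    return image, GroundTruth(records, _spec_dict_movie(spec))


def _spec_dict_movie(spec: TransportMovieSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["path"] = np.asarray(spec.path).tolist()
    d["__spec__"] = "TransportMovieSpec"
    return d


# ---------------------------------------------------------------------------
# EM sections
# ---------------------------------------------------------------------------


@dataclass
class EMSectionSpec:
    """Elliptical vesicle profiles in an EM section, as an integer label image.

    Long diameters and elongations (long/short, >= 1) are drawn from normal
    distributions; defaults match tubule-shaped immature precursor profiles
    (~72 nm long diameter, elongation ~1.8).
    """

    n_objects: int = 50
    long_diameter_nm: Tuple[float, float] = (72.0, 10.0)  # mean, sd
    elongation: Tuple[float, float] = (1.79, 0.25)  # mean, sd; clipped >= 1
    region_shape_px: Tuple[int, int] = (512, 512)
    pixel_size: float = 2.0  # nm/px
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        if self.elongation[0] < 1:
            raise ValueError("mean elongation must be >= 1")


def generate_em_sections(spec: EMSectionSpec) -> Tuple[CalibratedImage, GroundTruth]:
    """Render non-overlapping labeled ellipses; truth lists drawn axes and areas."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.region_shape_px
    labels = np.zeros((h, w), dtype=np.int32)
    rows = []
    yy, xx = np.mgrid[0:h, 0:w]
    for i in range(spec.n_objects):
        for attempt in range(_MAX_PLACEMENT_TRIES):
            long_d = max(rng.normal(*spec.long_diameter_nm), 4 * spec.pixel_size)
            elong = max(rng.normal(*spec.elongation), 1.0)
            short_d = long_d / elong
            a = long_d / 2 / spec.pixel_size  # semi-axes in px
            b = short_d / 2 / spec.pixel_size
            theta = rng.uniform(0, np.pi)
            margin = a + 1
            cx = rng.uniform(margin, w - 1 - margin)
            cy = rng.uniform(margin, h - 1 - margin)
            ct, st = np.cos(theta), np.sin(theta)
            u = (xx - cx) * ct + (yy - cy) * st
            v = -(xx - cx) * st + (yy - cy) * ct
            inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            if not (labels[inside] != 0).any():
                labels[inside] = i + 1
                rows.append(
                    (
                        i + 1,
                        long_d,
                        short_d,
                        long_d / short_d,
                        np.pi * (long_d / 2) * (short_d / 2),
                        cx,
                        cy,
                        np.rad2deg(theta),
                    )
                )
                break
        else:
            raise InfeasibleDensityError(
                f"could not pack {spec.n_objects} ellipses (placed {len(rows)})"
            )
    records = pd.DataFrame(
        rows,
        columns=[
            "label",
            "long_diameter_nm",
            "short_diameter_nm",
            "elongation",
            "area_nm2",
            "cx_px",
            "cy_px",
            "angle_deg",
        ],
    )
    image = CalibratedImage(
        labels.astype(np.float64),
        Calibration(spec.pixel_size, pixel_unit="nm"),
        "YX",
    )
    return image, GroundTruth(records, _spec_dict(spec))


@dataclass
class SphereSectionSpec:
    """Random planar sections through a slab packed with equal spheres.

    Used as the simulation oracle for the Delesse areal-fraction estimator:
    sphere centers are placed without overlap in a box that is periodic along
    z, so the expected areal fraction of any horizontal section equals the
    true volume fraction exactly.
    """

    volume_fraction: float = 0.02
    sphere_radius_nm: float = 30.0
    box_nm: float = 2000.0
    n_sections: int = 100
    pixel_size: float = 2.0  # nm/px
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.volume_fraction < 0.2:
            raise ValueError("volume_fraction must be in [0, 0.2) for rejection packing")


def generate_sphere_sections(
    spec: SphereSectionSpec,
) -> Tuple[List[np.ndarray], GroundTruth]:
    """Return a list of 2D label images (one per random section) plus truth."""
    rng = np.random.default_rng(spec.seed)
    r = spec.sphere_radius_nm
    box = spec.box_nm
    v_sphere = 4.0 / 3.0 * np.pi * r**3
    n_spheres = int(round(spec.volume_fraction * box**3 / v_sphere))
    centers = np.empty((n_spheres, 3))
    count = 0
    for i in range(n_spheres):
        for attempt in range(_MAX_PLACEMENT_TRIES):
            c = rng.uniform(0, box, size=3)
            # lateral non-overlap plain, z periodic
            if count:
                d = centers[:count] - c
                d[:, 2] -= box * np.round(d[:, 2] / box)
                if np.min(np.sum(d**2, axis=1)) < (2 * r) ** 2:
                    continue
            centers[count] = c
            count += 1
            break
        else:
            raise InfeasibleDensityError("sphere packing failed")

    npx = int(round(box / spec.pixel_size))
    yy, xx = np.mgrid[0:npx, 0:npx]
    sections: List[np.ndarray] = []
    fracs = []
    for k in range(spec.n_sections):
        z = rng.uniform(0, box)
        dz = centers[:, 2] - z
        dz -= box * np.round(dz / box)
        hit = np.abs(dz) < r
        label = np.zeros((npx, npx), dtype=np.int32)
        lab = 0
        for (cx, cy, _), d in zip(centers[hit], dz[hit]):
            rc = np.sqrt(r**2 - d**2) / spec.pixel_size
            lab += 1
            cxp, cyp = cx / spec.pixel_size, cy / spec.pixel_size
            y0, y1 = max(0, int(cyp - rc) - 1), min(npx, int(cyp + rc) + 2)
            x0, x1 = max(0, int(cxp - rc) - 1), min(npx, int(cxp + rc) + 2)
            sub = (xx[y0:y1, x0:x1] - cxp) ** 2 + (yy[y0:y1, x0:x1] - cyp) ** 2 <= rc**2
            label[y0:y1, x0:x1][sub] = lab
        sections.append(label)
        fracs.append(float(np.count_nonzero(label)) / label.size)
    records = pd.DataFrame(
        {"section": np.arange(spec.n_sections), "areal_fraction": fracs}
    )
    return sections, GroundTruth(records, _spec_dict(spec))


# ---------------------------------------------------------------------------
# Evoked-current traces
# ---------------------------------------------------------------------------


@dataclass
class EphysTraceSpec:
    """Double-exponential evoked synaptic current trace.

    Each stimulus adds ``amplitude * norm * (exp(-t/decay_tau) -
    exp(-t/rise_tau))`` with ``norm`` chosen so the transient's peak equals
    ``amplitude`` exactly. Inward currents are negative. Defaults emulate
    two-electrode voltage-clamp recordings: 10 kHz sampling, -75 nA peak,
    tau_decay 5.5 ms.
    """

    sample_rate: float = 10000.0  # Hz
    duration: float = 0.2  # s
    baseline: float = 0.0  # nA
    amplitude: float = -75.0  # nA, signed
    rise_tau: float = 0.5  # ms
    decay_tau: float = 5.5  # ms
    stim_times: Tuple[float, ...] = (0.05,)  # s
    noise_sd: float = 0.0  # nA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if not self.decay_tau > self.rise_tau > 0:
            raise ValueError("require decay_tau > rise_tau > 0")


def biexp_kernel(t_ms: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials kernel; t in ms, 0 before onset."""
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    peak = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    k = np.where(
        t_ms >= 0,
        np.exp(-np.clip(t_ms, 0, None) / decay_tau)
        - np.exp(-np.clip(t_ms, 0, None) / rise_tau),
        0.0,
    )
    return k / peak


def generate_ephys_trace(spec: EphysTraceSpec) -> Tuple[pd.DataFrame, GroundTruth]:
    """Generate a trace as a DataFrame (time_s, current_nA) plus truth."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration, 1.0 / spec.sample_rate)
    current = np.full_like(t, spec.baseline)
    for ts in spec.stim_times:
        current += spec.amplitude * biexp_kernel(
            (t - ts) * 1000.0, spec.rise_tau, spec.decay_tau
        )
    if spec.noise_sd > 0:
        current = current + rng.normal(0.0, spec.noise_sd, size=t.shape)
    trace = pd.DataFrame({"time_s": t, "current_nA": current})
    records = pd.DataFrame(
        {
            "stim_time_s": list(spec.stim_times),
            "amplitude_nA": spec.amplitude,
            "rise_tau_ms": spec.rise_tau,
            "decay_tau_ms": spec.decay_tau,
            "baseline_nA": spec.baseline,
        }
    )
    return trace, GroundTruth(records, _spec_dict(spec))
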