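"""Ground-truth recovery benchmarks on synthetic data.

Because the study's raw recordings are not deposited, every stage of the
pipeline is validated property-based: the synthetic generators produce
inputs with known ground truth and these routines measure how well each
analysis recovers it. They are used by the test suite and by the
reproduction script; all randomness is controlled by the ``seed`` argument.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Dict, List

import numpy as np
from scipy import stats as sps

from . import ephys as ephys_mod
from . import morphometry as mm
from . import spatial, synthdata as sd, transport as tp
from .coloc import pearson_above_threshold
from .core import RegionOfInterest
from .quantify import DetectionConfig, ring_diameter, segment_particles
from .stats import route_and_test


def eval_puncta_count(seed: int = 1) -> Dict[str, float]:
    """Detection count recovery on a 200-spot field at peak SNR ~5."""
    spec = sd.PunctaFieldSpec(n_puncta=200, min_separation=8.0, seed=seed)
    img, truth = sd.generate_puncta_field(spec)
    cfg = DetectionConfig(threshold=60.0, min_particle_area=9, maxima_prominence=40.0)
    table = segment_particles(img, cfg=cfg)
    n_true = len(truth.records)
    return {
        "n_true": float(n_true),
        "n_detected": float(table.n_particles),
        "rel_error": abs(table.n_particles - n_true) / n_true,
    }


def eval_intensity_conservation(seed: int = 2) -> Dict[str, float]:
    """Noiseless field: summed per-particle integrated density vs truth."""
    spec = sd.PunctaFieldSpec(n_puncta=50, seed=seed, noise=sd.NOISE_OFF)
    img, truth = sd.generate_puncta_field(spec)
    cfg = DetectionConfig(
        threshold=0.5, background_method="percentile", background_percentile=1,
        maxima_prominence=20.0,
    )
    table = segment_particles(img, cfg=cfg)
    measured = float(table.particles.integrated_density_au.sum())
    expected = float(truth.records.integrated_intensity_au.sum())
    return {
        "measured": measured,
        "expected": expected,
        "rel_error": abs(measured - expected) / expected,
    }


def eval_ring_diameter() -> Dict[str, float]:
    """Rasterized 0.14 µm disk -> equivalent diameter vs 0.28 µm closed form."""
    px = 0.004
    r_px = 0.14 / px
    yy, xx = np.mgrid[0:80, 0:80]
    area = float((((xx - 40) ** 2 + (yy - 40) ** 2) <= r_px**2).sum()) * px**2
    d = float(ring_diameter(area))
    return {"diameter_um": d, "rel_error": abs(d - 0.28) / 0.28}


def eval_coloc(seed: int = 3, n_reps: int = 20) -> Dict[str, object]:
    """Pearson calibration: identity, independent null, shared-fraction sweep."""
    seeds = np.random.default_rng(seed)

    def sub() -> int:
        return int(seeds.integers(0, 2**31))

    img, _ = sd.generate_puncta_field(sd.PunctaFieldSpec(n_puncta=120, seed=sub()))
    r_ident = pearson_above_threshold(img.data, img.data).r_data

    null_rs = []
    for k in range(5):
        a, _ = sd.generate_puncta_field(
            sd.PunctaFieldSpec(n_puncta=150, seed=sub())
        )
        b, _ = sd.generate_puncta_field(
            sd.PunctaFieldSpec(n_puncta=150, seed=sub())
        )
        res = pearson_above_threshold(
            a.data, b.data,
            thr1=float(a.data.min()) - 1.0, thr2=float(b.data.min()) - 1.0,
        )
        assert res.n_pixels_used >= 10_000
        null_rs.append(res.r_data)

    sweep = []
    for f in (0.0, 0.25, 0.5, 0.75, 1.0):
        rs = []
        for rep in range(n_reps):
            im, _ = sd.generate_two_channel_field(
                sd.TwoChannelSpec(
                    base=sd.PunctaFieldSpec(n_puncta=100, seed=sub()),
                    shared_fraction=f,
                )
            )
            rs.append(pearson_above_threshold(im.data[0], im.data[1]).r_data)
        sweep.append(float(np.mean(rs)))
    return {
        "r_identical": float(r_ident),
        "null_abs_max": float(np.max(np.abs(null_rs))),
        "sweep_means": sweep,
        "sweep_monotone": bool(all(a <= b + 1e-12 for a, b in zip(sweep, sweep[1:]))),
    }


def eval_center_distance(seed: int = 4) -> Dict[str, object]:
    """Median center-of-mass distance vs generated offsets {0, 0.24, 0.48} µm."""
    px = 0.04
    out = {}
    seeds = np.random.default_rng(seed)
    for offset in (0.0, 0.24, 0.48):
        ds: List[float] = []
        while len(ds) < 30:
            base = sd.PunctaFieldSpec(
                image_shape=(192, 192), pixel_size=px, n_puncta=6,
                min_separation=25, seed=int(seeds.integers(0, 2**31)),
                noise=sd.NoiseModel(1.0, 6.0),
            )
            img, truth = sd.generate_two_channel_field(
                sd.TwoChannelSpec(base=base, mode="center_offset",
                                  center_offset=offset, offset_direction=30.0)
            )
            for _, r in truth.records.iterrows():
                sq = 12
                roi1 = RegionOfInterest("polygon", [
                    (r.x1_px - sq, r.y1_px - sq), (r.x1_px + sq, r.y1_px - sq),
                    (r.x1_px + sq, r.y1_px + sq), (r.x1_px - sq, r.y1_px + sq)])
                roi2 = RegionOfInterest("polygon", [
                    (r.x2_px - sq, r.y2_px - sq), (r.x2_px + sq, r.y2_px - sq),
                    (r.x2_px + sq, r.y2_px + sq), (r.x2_px - sq, r.y2_px + sq)])
                ds.append(
                    spatial.center_distance(
                        img.data[0], img.data[1], roi1, roi2, px, 30.0, 30.0
                    ).d
                )
        med = float(np.median(ds[:30]))
        out[f"median_um_at_{offset}"] = med
        out[f"error_px_at_{offset}"] = abs(med - offset) / px
    out["max_error_px"] = max(
        out[f"error_px_at_{o}"] for o in (0.0, 0.24, 0.48)
    )
    return out


def eval_peak_to_peak(seed: int = 5) -> Dict[str, object]:
    """Offset-0.4 µm fields: modal histogram bin and shift-null spread ratio."""
    px = 0.04
    data, null = [], []
    seeds = np.random.default_rng(seed)
    for _ in range(12):
        base = sd.PunctaFieldSpec(
            image_shape=(256, 256), pixel_size=px, n_puncta=12,
            min_separation=22, seed=int(seeds.integers(0, 2**31)),
            noise=sd.NoiseModel(1.0, 6.0),
        )
        img, truth = sd.generate_two_channel_field(
            sd.TwoChannelSpec(base=base, mode="center_offset",
                              center_offset=0.4, offset_direction=20.0)
        )
        th = np.deg2rad(20.0)
        lines = []
        for _, r in truth.records.iterrows():
            p0 = (r.x1_px - 45 * np.cos(th), r.y1_px - 45 * np.sin(th))
            p1 = (r.x1_px + 55 * np.cos(th), r.y1_px + 55 * np.sin(th))
            pts = np.array([p0, p1])
            if (pts < 1).any() or (pts > 254).any():
                continue
            lines.append(RegionOfInterest("line", [p0, p1]))
        d = spatial.peak_distance_distribution(img.data[0], img.data[1], lines, px)
        data.append(d.distances_um)
        null.append(d.null_distances_um)
    dist = spatial.DistanceDistribution(np.concatenate(data), np.concatenate(null))
    hist = dist.histogram()
    modal = hist.loc[hist.data_pct.idxmax()]
    dd = dist.distances_um[dist.distances_um <= 1.2]
    nn = dist.null_distances_um[dist.null_distances_um <= 1.2]
    return {
        "modal_bin_left_um": float(modal.bin_left_um),
        "modal_bin_right_um": float(modal.bin_right_um),
        "modal_pct": float(modal.data_pct),
        "n_data": int(len(dd)),
        "n_null": int(len(nn)),
        "spread_ratio": float(nn.std() / dd.std()) if len(nn) > 1 else np.nan,
    }


def _single_particle_track(seed: int, velocity: float, **kw):
    spec = sd.TransportMovieSpec(
        n_particles=1, velocity_range=(velocity, velocity), seed=seed, **kw
    )
    movie, truth = sd.generate_transport_movie(spec)
    path = RegionOfInterest("polyline", spec.path)
    kymo = tp.build_kymograph(movie, path, width=3)
    tracks = tp.detect_tracks(kymo)
    return spec, movie, truth, kymo, tracks


def eval_transport(seed: int = 6) -> Dict[str, object]:
    """Speed/direction recovery, cotransport fraction, boundary gates."""
    rng = np.random.default_rng(seed)
    errs, missed, dir_errors = [], 0, 0
    for k in range(50):
        v = float(rng.uniform(0.3, 1.2)) * (1 if k % 2 == 0 else -1)
        _, _, truth, _, tracks = _single_particle_track(
            int(rng.integers(0, 2**31)), v
        )
        if len(tracks) != 1:
            missed += 1
            continue
        t = tracks[0]
        errs.append(abs(t.speed_um_s - abs(v)) / abs(v))
        want = "anterograde" if v >= 0 else "retrograde"
        dir_errors += t.direction != want

    co_pos, co_n = 0, 0
    for k in range(40):
        spec = sd.TransportMovieSpec(
            n_particles=1, cotransport_fraction=0.5,
            seed=int(rng.integers(0, 2**31)),
        )
        movie, truth = sd.generate_transport_movie(spec)
        path = RegionOfInterest("polyline", spec.path)
        k1 = tp.build_kymograph(movie, path, width=3)
        k2 = tp.build_kymograph(movie, path, width=3, channel=1)
        tracks = tp.detect_tracks(k1)
        if len(tracks) != 1:
            continue
        rec = tp.classify_cotransport(tracks[0], k2)
        co_n += 1
        co_pos += bool(rec.co_positive)
    ci_lo = sps.binom.ppf(0.025, co_n, 0.5) / co_n if co_n else np.nan
    ci_hi = sps.binom.ppf(0.975, co_n, 0.5) / co_n if co_n else np.nan

    # boundary gates: exactly 4 µm over exactly 30 s
    _, _, _, _, btracks = _single_particle_track(
        int(rng.integers(0, 2**31)), 4.0 / 30.0, n_frames=31
    )
    # just below either gate: 3 µm over 30 s
    _, _, _, _, rtracks = _single_particle_track(
        int(rng.integers(0, 2**31)), 3.0 / 30.0, n_frames=31
    )
    return {
        "n_tracked": 50 - missed,
        "median_speed_error": float(np.median(errs)),
        "direction_errors": int(dir_errors),
        "co_fraction": co_pos / co_n if co_n else np.nan,
        "co_n": co_n,
        "co_in_ci": bool(ci_lo <= co_pos / co_n <= ci_hi) if co_n else False,
        "boundary_accepted": len(btracks) == 1,
        "below_boundary_rejected": len(rtracks) == 0,
    }


def eval_morphometry(seed: int = 7) -> Dict[str, float]:
    """Ellipse elongation, voxel sphere volume/surface, Delesse estimator."""
    spec = sd.EMSectionSpec(
        n_objects=1, long_diameter_nm=(72.0, 0.0), elongation=(72 / 41, 0.0),
        region_shape_px=(256, 256), pixel_size=0.5, seed=seed,
    )
    img, _ = sd.generate_em_sections(spec)
    elong = float(mm.fit_shape(img.data, 0.5).elongation.iloc[0])

    r, n = 30, 68
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
    c = (n - 1) / 2
    ball = (((xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2) <= r * r).astype(int)
    df3 = mm.volume_surface_3d(ball, 1.0)
    v_true, s_true = 4 / 3 * np.pi * r**3, 4 * np.pi * r**2

    sections, _ = sd.generate_sphere_sections(
        sd.SphereSectionSpec(n_sections=100, seed=seed)
    )
    fracs = [mm.volume_fraction(s).volume_fraction for s in sections]
    return {
        "elongation": elong,
        "elongation_rel_error": abs(elong - 72 / 41) / (72 / 41),
        "volume_rel_error": abs(df3.volume.iloc[0] - v_true) / v_true,
        "surface_rel_error": abs(df3.surface_area.iloc[0] - s_true) / s_true,
        "delesse_mean": float(np.mean(fracs)),
        "delesse_rel_error": abs(np.mean(fracs) - 0.02) / 0.02,
    }


def eval_ephys(seed: int = 8) -> Dict[str, float]:
    """Amplitude/tau/paired-pulse recovery on low-noise traces."""
    trace, _ = sd.generate_ephys_trace(sd.EphysTraceSpec(noise_sd=0.2, seed=seed))
    m = ephys_mod.evoked_metrics(trace, 0.05, (0.0, 0.05))
    pp_trace, _ = sd.generate_ephys_trace(
        sd.EphysTraceSpec(stim_times=(0.05, 0.06), noise_sd=0.2, seed=seed + 1)
    )
    pp = ephys_mod.pp_ratio(pp_trace, 0.05, 0.06)
    return {
        "amplitude_nA": m.amplitude_nA,
        "amplitude_rel_error": abs(m.amplitude_nA - (-75.0)) / 75.0,
        "decay_tau_ms": m.decay_tau_ms,
        "tau_rel_error": abs(m.decay_tau_ms - 5.5) / 5.5,
        "charge_pC": m.charge_pC,
        "pp_ratio_10ms": float(pp["pp_ratio"]),
        "pp_abs_error": abs(float(pp["pp_ratio"]) - 1.0),
    }


def eval_stats_routing(seed: int = 9, n_reps: int = 1000) -> Dict[str, object]:
    """Type-I rate of the routed two-group test plus routing-table checks."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_reps):
        g = {"a": rng.normal(0, 1, 20), "b": rng.normal(0, 1, 20)}
        rej += route_and_test(g).p_values.p.iloc[0] < 0.05
    lo = sps.binom.ppf(0.025, n_reps, 0.05) / n_reps
    hi = sps.binom.ppf(0.975, n_reps, 0.05) / n_reps
    routes = {
        "two_normal": route_and_test(
            {"a": rng.normal(0, 1, 20), "b": rng.normal(0, 1, 20)}
        ).test_used,
        "two_mixed": route_and_test(
            {"a": rng.normal(0, 1, 50), "b": rng.lognormal(0, 1.5, 50)}
        ).test_used,
        "three_normal": route_and_test(
            {k: rng.normal(0, 1, 25) for k in "abc"}
        ).test_used,
        "three_mixed": route_and_test(
            {"a": rng.normal(0, 1, 30), "b": rng.lognormal(0, 1.5, 30),
             "c": rng.normal(0, 1, 30)}
        ).test_used,
    }
    return {
        "type1_rate": rej / n_reps,
        "ci_lo": float(lo),
        "ci_hi": float(hi),
        "in_ci": bool(lo <= rej / n_reps <= hi),
        "routes": routes,
        "routes_ok": routes == {
            "two_normal": "t", "two_mixed": "mann_whitney",
            "three_normal": "anova_tukey", "three_mixed": "kruskal_dunn",
        },
    }


def eval_determinism(seed: int = 10, workdir: Path | str = ".") -> Dict[str, object]:
    """Seeded simulate->quantify->stats run twice: byte-identical CSVs."""
    from .pipeline import RunConfig, run_pipeline

    workdir = Path(workdir)

    def run_once(name: str) -> Dict[str, str]:
        cfg = RunConfig(
            stages=["simulate", "quantify", "stats"], seed=seed,
            out_dir=str(workdir / name),
            simulate={"n_fields": 4, "n_puncta": 60},
            quantify={"threshold": 60.0, "min_particle_area": 9,
                      "background_method": "percentile"},
        )
        out = run_pipeline(cfg)
        return {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.glob("*.csv"))
        }

    h1, h2 = run_once("run1"), run_once("run2")
    return {"identical": h1 == h2, "n_files": len(h1)}
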