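"""Puncta detection: projection, maxima/watershed, statistics, ring diameter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from synaptoquant import synthdata as sd
from synaptoquant.core import CalibratedImage, Calibration, RegionOfInterest
from synaptoquant.quantify import (
    DetectionConfig,
    cytoplasmic_intensity,
    find_maxima,
    project_stack,
    ring_diameter,
    segment_particles,
    summarize_field,
)

CAL = Calibration(0.1)


def _img(arr, axes="YX"):
    return CalibratedImage(np.asarray(arr, float), CAL, axes)


class TestProjection:
    def test_single_slice_identity(self):
        stack = _img(np.arange(12.0).reshape(1, 3, 4), "ZYX")
        proj = project_stack(stack)
        assert np.array_equal(proj.data, stack.data[0])

    def test_pixelwise_max(self):
        stack = _img(np.stack([np.full((2, 2), 3.0), np.full((2, 2), 7.0)]), "ZYX")
        assert np.all(project_stack(stack).data == 7.0)

    def test_subrange_matches_brute_force(self):
        rng = np.random.default_rng(0)
        data = rng.random((40, 16, 16))
        stack = _img(data, "ZYX")
        proj = project_stack(stack, (10, 30))
        assert np.array_equal(proj.data, data[10:30].max(axis=0))
        # independent of excluded slices
        data2 = data.copy()
        data2[:10] += 100
        assert np.array_equal(
            project_stack(_img(data2, "ZYX"), (10, 30)).data, proj.data
        )

    def test_empty_range_raises(self):
        stack = _img(np.zeros((4, 4, 4)), "ZYX")
        with pytest.raises(ValueError):
            project_stack(stack, (2, 2))


class TestSegmentation:
    def test_count_recovery_on_noisy_field(self, snr5_field):
        spec, img, truth = snr5_field
        cfg = DetectionConfig(
            threshold=60.0, min_particle_area=9, maxima_prominence=40.0
        )
        table = segment_particles(img, cfg=cfg)
        assert abs(table.n_particles - 200) / 200 <= 0.05

    def test_touching_gaussians_split_between_centroids(self):
        # two spots whose threshold masks touch but carry two clear maxima
        spec = sd.PunctaFieldSpec(
            n_puncta=0, image_shape=(48, 48), background=0.0, noise=sd.NOISE_OFF
        )
        img, _ = sd.generate_puncta_field(spec)
        from synaptoquant.synthdata import _render_gaussian_spots

        centers = np.array([[18.0, 24.0], [30.0, 24.0]])
        data = _render_gaussian_spots((48, 48), centers, np.array([100.0, 100.0]), 3.0)
        cimg = _img(data)
        cfg = DetectionConfig(
            threshold=5.0, background_method="none", maxima_prominence=10.0,
            min_particle_area=4,
        )
        table = segment_particles(cimg, cfg=cfg)
        assert table.n_particles == 2
        xs = np.sort(table.particles.x_px.to_numpy())
        assert xs[0] < 24.0 < xs[1]
        # dividing line between the two centroids: no particle mask crosses
        labels = table.labels
        left_label = labels[24, 18]
        right_label = labels[24, 30]
        assert left_label != right_label
        assert not np.any(labels[:, :22] == right_label)
        assert not np.any(labels[:, 27:] == left_label)

    def test_uniform_image_below_threshold_empty(self):
        cimg = _img(np.full((32, 32), 5.0))
        cfg = DetectionConfig(threshold=50.0, background_method="none")
        table = segment_particles(cimg, cfg=cfg)
        assert table.n_particles == 0

    def test_watershed_partition(self, noiseless_field):
        _, img, _ = noiseless_field
        cfg = DetectionConfig(
            threshold=5.0, background_method="percentile", background_percentile=1,
            maxima_prominence=20.0, min_particle_area=1,
        )
        table = segment_particles(img, cfg=cfg)
        # particle masks are disjoint by construction (label image) and
        # their union equals the threshold mask
        from synaptoquant.quantify import subtract_background

        bgsub = subtract_background(img.data, cfg)
        mask = bgsub > 5.0
        assert np.array_equal(table.labels > 0, mask)

    def test_threshold_monotonicity(self, snr5_field):
        _, img, _ = snr5_field
        from synaptoquant.quantify import subtract_background

        cfg = DetectionConfig(threshold=0.0)
        bgsub = subtract_background(img.data, cfg)
        areas = [(bgsub > thr).sum() for thr in (20.0, 40.0, 60.0, 80.0)]
        assert all(a >= b for a, b in zip(areas, areas[1:]))


def _dynamics_maxima(img, conn_full=True):
    """Exhaustive prominence (dynamics) of every regional maximum via
    union-find over pixels in decreasing-value order."""
    H, W = img.shape
    order = np.argsort(img.ravel())[::-1]
    parent = np.arange(H * W)
    peak = img.ravel().copy()
    peakpix = np.arange(H * W)
    added = np.zeros(H * W, bool)
    dyn = {}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    nbrs = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (0, 0)]
    for idx in order:
        y, x = divmod(idx, W)
        added[idx] = True
        for dy, dx in nbrs:
            ny, nx = y + dy, x + dx
            if 0 <= ny < H and 0 <= nx < W and added[ny * W + nx]:
                r1, r2 = find(idx), find(ny * W + nx)
                if r1 != r2:
                    lo, hi = (r1, r2) if peak[r1] < peak[r2] else (r2, r1)
                    dyn[peakpix[lo]] = peak[lo] - img[y, x]
                    parent[lo] = hi
    dyn[peakpix[find(order[0])]] = np.inf
    return dyn


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), h=st.floats(0.05, 0.6))
def test_prominence_maxima_match_exhaustive_oracle(seed, h):
    """On small images, h-maxima detection equals brute-force dynamics."""
    rng = np.random.default_rng(seed)
    img = rng.random((12, 12))
    markers = find_maxima(img, h)
    n_found = ndimage.label(markers, structure=np.ones((3, 3)))[1]
    dyn = _dynamics_maxima(img)
    n_expected = sum(1 for v in dyn.values() if v >= h)
    assert n_found == n_expected


class TestSummaries:
    def test_density_exact(self, noiseless_field):
        _, img, _ = noiseless_field
        cfg = DetectionConfig(
            threshold=5.0, background_method="percentile", background_percentile=1,
            maxima_prominence=20.0,
        )
        table = segment_particles(img, cfg=cfg)
        s = summarize_field(table, reference_area_um2=5.0)
        assert s["density_per_um2"] == table.n_particles / 5.0

    def test_self_normalization_is_100(self):
        import pandas as pd

        from synaptoquant.quantify import ParticleTable

        parts = pd.DataFrame(
            {"integrated_density_au": [10.0, 20.0], "area_um2": [1.0, 2.0]}
        )
        t = ParticleTable(parts)
        s = summarize_field(t, 4.0)
        s2 = summarize_field(
            t, 4.0, control_mean={"density_per_um2": s["density_per_um2"]}
        )
        assert s2["density_per_um2_pct_of_control"] == pytest.approx(100.0)

    def test_sum_intensity_matches_truth_noiseless(self, noiseless_field):
        spec, img, truth = noiseless_field
        cfg = DetectionConfig(
            threshold=0.5, background_method="percentile", background_percentile=1,
            maxima_prominence=20.0,
        )
        table = segment_particles(img, cfg=cfg)
        area = img.data.size * spec.pixel_size**2
        s = summarize_field(table, area)
        expected = truth.records.integrated_intensity_au.sum() / area
        assert s["sum_intensity_per_area_au_um2"] == pytest.approx(expected, rel=0.01)

    def test_zero_control_raises(self, noiseless_field):
        _, img, _ = noiseless_field
        table = segment_particles(img, cfg=DetectionConfig(threshold=5.0,
                                  background_method="none"))
        with pytest.raises(ValueError):
            summarize_field(table, 1.0, control_mean={"density_per_um2": 0.0})


class TestRingDiameter:
    def test_closed_form(self):
        assert ring_diameter(np.pi) == pytest.approx(2.0)
        assert ring_diameter(0.0) == 0.0

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            ring_diameter(-1.0)

    def test_pixelated_disk(self):
        # disk of radius 0.14 µm rasterized at 4 nm/px
        px = 0.004
        r_px = 0.14 / px
        yy, xx = np.mgrid[0:80, 0:80]
        disk = ((xx - 40) ** 2 + (yy - 40) ** 2) <= r_px**2
        area_um2 = disk.sum() * px**2
        assert ring_diameter(area_um2) == pytest.approx(0.28, rel=0.02)


class TestCytoplasmicIntensity:
    def _bouton(self):
        pts = [(4.0, 4.0), (44.0, 4.0), (44.0, 44.0), (4.0, 44.0)]
        return RegionOfInterest("polygon", pts)

    def test_no_bright_regions_mean_over_bouton(self):
        img = _img(np.full((48, 48), 12.0))
        res = cytoplasmic_intensity(img, self._bouton(), az_threshold=30.0)
        assert res["mean_cytoplasmic_intensity_au"] == pytest.approx(12.0)
        assert res["excluded_area_fraction"] == 0.0

    def test_bright_spots_excluded(self):
        from synaptoquant.synthdata import _render_gaussian_spots

        data = np.full((48, 48), 50.0)
        data += _render_gaussian_spots(
            (48, 48), np.array([[15.0, 15.0], [32.0, 30.0]]),
            np.array([500.0, 500.0]), 2.0,
        )
        res = cytoplasmic_intensity(
            _img(data), self._bouton(), blur_sigma=2.0, az_threshold=80.0
        )
        assert res["mean_cytoplasmic_intensity_au"] == pytest.approx(50.0, rel=0.05)
        assert res["excluded_area_fraction"] > 0.0

    def test_fully_bright_bouton_raises(self):
        img = _img(np.full((48, 48), 100.0))
        with pytest.raises(ValueError, match="cytoplasmic"):
            cytoplasmic_intensity(img, self._bouton(), az_threshold=30.0)
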