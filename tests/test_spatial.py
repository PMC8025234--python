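"""Line profiles, peak-to-peak distances with shift null, center distances."""

import numpy as np
import pytest

from synaptoquant import synthdata as sd
from synaptoquant.core import RegionOfInterest
from synaptoquant.spatial import (
    DistanceDistribution,
    center_distance,
    line_profile,
    peak_distance_distribution,
    peak_to_peak,
    shifted_null,
)


def _line(p0, p1):
    return RegionOfInterest("line", [p0, p1])


class TestLineProfile:
    def test_constant_image_constant_profile(self):
        img = np.full((32, 64), 7.0)
        pos, vals = line_profile(img, _line((2, 16), (60, 16)))
        assert np.allclose(vals, 7.0)
        assert pos[0] == 0.0

    def test_peak_at_spot_path_coordinate(self):
        from synaptoquant.synthdata import _render_gaussian_spots

        img = _render_gaussian_spots((64, 64), np.array([[40.0, 32.0]]),
                                     np.array([100.0]), 2.0)
        pos, vals = line_profile(img, _line((10, 32), (60, 32)), pixel_size=1.0)
        assert pos[np.argmax(vals)] == pytest.approx(30.0, abs=0.5)

    def test_width_invariance_on_perpendicular_constant_image(self):
        img = np.tile(np.sin(np.arange(64) / 5.0) + 2.0, (32, 1))
        line = _line((2, 16), (60, 16))
        _, v1 = line_profile(img, line, width=1)
        _, v3 = line_profile(img, line, width=3)
        assert np.allclose(v1, v3)

    def test_degenerate_line_raises(self):
        with pytest.raises(ValueError):
            line_profile(np.zeros((8, 8)), _line((3, 3), (3, 3)))


class TestPeakToPeak:
    def test_identical_profiles_zero(self):
        x = np.arange(50.0) * 0.1
        v = np.exp(-((x - 2.5) ** 2))
        assert peak_to_peak((x, v), (x, v)) == 0.0

    def test_offset_gaussians(self):
        x = np.arange(100.0) * 0.04
        v1 = np.exp(-((x - 1.6) ** 2) / 0.02)
        v2 = np.exp(-((x - 2.0) ** 2) / 0.02)
        assert peak_to_peak((x, v1), (x, v2)) == pytest.approx(0.4, abs=0.02)

    def test_flat_profile_raises(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="no peak"):
            peak_to_peak((x, np.zeros(10)), (x, np.ones(10)))


class TestShiftedNull:
    def test_shift_by_width_is_identity(self):
        rng = np.random.default_rng(1)
        img = rng.random((16, 32))
        assert np.array_equal(shifted_null(img, 32), img)

    def test_composition(self):
        rng = np.random.default_rng(2)
        img = rng.random((16, 100))
        assert np.array_equal(
            shifted_null(shifted_null(img, 40), 40), shifted_null(img, 80)
        )


@pytest.fixture(scope="module")
def offset_field_lines():
    """Paired field at 0.4 µm offset plus auto-placed lines through pairs."""
    all_imgs = []
    for s in range(4):
        base = sd.PunctaFieldSpec(
            image_shape=(256, 256), pixel_size=0.04, n_puncta=10,
            min_separation=22, seed=400 + s, noise=sd.NoiseModel(1.0, 6.0),
        )
        spec = sd.TwoChannelSpec(base=base, mode="center_offset",
                                 center_offset=0.4, offset_direction=20.0)
        img, truth = sd.generate_two_channel_field(spec)
        th = np.deg2rad(20.0)
        lines = []
        for _, r in truth.records.iterrows():
            p0 = (r.x1_px - 45 * np.cos(th), r.y1_px - 45 * np.sin(th))
            p1 = (r.x1_px + 55 * np.cos(th), r.y1_px + 55 * np.sin(th))
            pts = np.array([p0, p1])
            if (pts < 1).any() or (pts > 254).any():
                continue
            lines.append(RegionOfInterest("line", [p0, p1]))
        all_imgs.append((img, truth, lines))
    return all_imgs


class TestDistributions:
    def test_modal_bin_and_null_spread(self, offset_field_lines):
        data, null = [], []
        for img, _, lines in offset_field_lines:
            d = peak_distance_distribution(img.data[0], img.data[1], lines, 0.04)
            data.append(d.distances_um)
            null.append(d.null_distances_um)
        dist = DistanceDistribution(np.concatenate(data), np.concatenate(null))
        hist = dist.histogram()
        modal = hist.loc[hist.data_pct.idxmax()]
        assert modal.bin_left_um == pytest.approx(0.36)
        assert modal.bin_right_um == pytest.approx(0.42)

    def test_histogram_frequencies_sum_to_100(self, offset_field_lines):
        img, _, lines = offset_field_lines[0]
        d = peak_distance_distribution(img.data[0], img.data[1], lines, 0.04)
        hist = d.histogram()
        assert hist.data_pct.sum() == pytest.approx(100.0, abs=0.1)

    def test_shared_field_data_mass_beats_null_in_first_bin(self):
        base = sd.PunctaFieldSpec(
            image_shape=(256, 256), pixel_size=0.04, n_puncta=10,
            min_separation=25, seed=77, noise=sd.NoiseModel(1.0, 6.0),
        )
        img, truth = sd.generate_two_channel_field(
            sd.TwoChannelSpec(base=base, shared_fraction=1.0)
        )
        lines = []
        for _, r in truth.records.iterrows():
            p0, p1 = (r.x1_px - 40, r.y1_px), (r.x1_px + 40, r.y1_px)
            if min(p0[0], r.y1_px) < 1 or p1[0] > 254:
                continue
            lines.append(RegionOfInterest("line", [p0, p1]))
        d = peak_distance_distribution(img.data[0], img.data[1], lines, 0.04)
        hist = d.histogram()
        first = hist.iloc[0]
        assert first.data_pct > first.null_pct


class TestCenterDistance:
    def test_same_channel_same_roi_zero(self):
        img, _ = sd.generate_puncta_field(
            sd.PunctaFieldSpec(n_puncta=5, seed=12, noise=sd.NOISE_OFF)
        )
        roi = RegionOfInterest(
            "polygon", [(5, 5), (250, 5), (250, 250), (5, 250)]
        )
        cd = center_distance(img.data, img.data, roi, roi, 0.1)
        assert cd.d == 0.0

    def test_offset_pair_recovery(self):
        base = sd.PunctaFieldSpec(
            image_shape=(192, 192), pixel_size=0.04, n_puncta=6,
            min_separation=25, seed=13, noise=sd.NoiseModel(1.0, 6.0),
        )
        img, truth = sd.generate_two_channel_field(
            sd.TwoChannelSpec(base=base, mode="center_offset",
                              center_offset=0.4, offset_direction=0.0)
        )
        ds = []
        for _, r in truth.records.iterrows():
            sq = 12
            roi1 = RegionOfInterest("polygon", [
                (r.x1_px - sq, r.y1_px - sq), (r.x1_px + sq, r.y1_px - sq),
                (r.x1_px + sq, r.y1_px + sq), (r.x1_px - sq, r.y1_px + sq)])
            roi2 = RegionOfInterest("polygon", [
                (r.x2_px - sq, r.y2_px - sq), (r.x2_px + sq, r.y2_px - sq),
                (r.x2_px + sq, r.y2_px + sq), (r.x2_px - sq, r.y2_px + sq)])
            ds.append(center_distance(img.data[0], img.data[1],
                                      roi1, roi2, 0.04, 30.0, 30.0).d)
        # 400 nm truth recovered within 20 nm (spec example in nm units)
        assert np.median(ds) == pytest.approx(0.4, abs=0.02)

    def test_translation_invariance(self):
        from synaptoquant.synthdata import _render_gaussian_spots

        a = _render_gaussian_spots((64, 64), np.array([[20.0, 30.0]]),
                                   np.array([50.0]), 2.0)
        b = _render_gaussian_spots((64, 64), np.array([[26.0, 30.0]]),
                                   np.array([50.0]), 2.0)
        roi = RegionOfInterest("polygon", [(5, 15), (45, 15), (45, 45), (5, 45)])
        d0 = center_distance(a, b, roi, roi, 1.0).d
        shift = np.roll(np.roll(a, 3, axis=0), 3, axis=1)
        shift_b = np.roll(np.roll(b, 3, axis=0), 3, axis=1)
        roi2 = RegionOfInterest("polygon", [(8, 18), (48, 18), (48, 48), (8, 48)])
        d1 = center_distance(shift, shift_b, roi2, roi2, 1.0).d
        assert d1 == pytest.approx(d0, abs=1e-9)

    def test_zero_intensity_raises(self):
        z = np.zeros((32, 32))
        roi = RegionOfInterest("polygon", [(2, 2), (30, 2), (30, 30), (2, 30)])
        with pytest.raises(ValueError):
            center_distance(z, z, roi, roi, 1.0)
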