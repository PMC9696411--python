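"""Center decoding, gap statistic, repair algorithm, crop geometry."""

import numpy as np
import pytest

from spinemark import (
    CropSpec,
    crop_sizes,
    crop_vertebra,
    extract_maxima,
    gap_check,
    gaussian_map,
    repair_centers,
)


def stack_with_peaks(points, sigma=1.5, shape=(64, 64)):
    return gaussian_map(points, sigma, shape).maps


class TestExtractMaxima:
    def test_recovers_annotated_centers(self):
        pts = [(31.0, 10.0), (32.0, 18.0), (31.0, 26.0), (33.0, 34.0), (32.0, 42.0), (32.0, 50.0)]
        stack = stack_with_peaks(pts)
        assert np.array_equal(extract_maxima(stack), np.asarray(pts))

    def test_row_major_tie_break(self):
        ch = np.zeros((1, 8, 8))
        ch[0, 2, 5] = 1.0
        ch[0, 6, 1] = 1.0
        assert tuple(extract_maxima(ch)[0]) == (5, 2)

    def test_constant_channel_falls_back_to_centroid(self):
        ch = np.ones((1, 9, 9))
        with pytest.warns(UserWarning, match="constant"):
            assert tuple(extract_maxima(ch)[0]) == (4.0, 4.0)


class TestGapCheck:
    def test_equal_gaps_not_flagged(self):
        pts = np.array([(32, 10), (32, 18), (32, 26), (32, 34), (32, 42), (32, 50)], dtype=float)
        g = gap_check(pts)
        assert not g.flagged
        assert np.allclose(g.d, 8.0)

    def test_hand_evaluated_flagged_case(self):
        # gaps 8,8,8,16,8 -> mean_rest 8; 16 > 11.2 -> flagged, j=4
        pts = np.array([(32, 10), (32, 18), (32, 26), (32, 34), (32, 50), (32, 58)], dtype=float)
        g = gap_check(pts)
        assert g.flagged and g.j == 4
        assert g.mean_rest == pytest.approx(8.0)
        assert g.d[g.j - 1] == pytest.approx(16.0)

    def test_coincident_maxima_not_flagged(self):
        pts = np.tile([(32.0, 30.0)], (6, 1))
        assert not gap_check(pts).flagged  # 0 > 0 is false

    def test_euclidean_gap_includes_x(self):
        pts = np.array([(10, 10), (10, 18), (10, 26), (10, 34), (40, 40), (40, 48)], dtype=float)
        g = gap_check(pts)
        assert g.d[3] == pytest.approx(np.hypot(30, 6))


class TestRepairCenters:
    def build_shifted_stack(self, blob_amp=0.5):
        """Channel maxima at y=(10,18,26,34,50,58) plus a weak blob at
        (32,42) in channel 4 — the worked scenario."""
        ys = [10, 18, 26, 34, 50, 58]
        stack = stack_with_peaks([(32.0, float(y)) for y in ys])
        weak = gaussian_map([(32.0, 42.0)], 1.5, (64, 64)).maps[0] * blob_amp
        stack[3] = np.maximum(stack[3], weak)
        return stack

    def test_worked_example_repaired_exactly(self):
        stack = self.build_shifted_stack()
        gap = gap_check(extract_maxima(stack))
        assert gap.flagged and gap.j == 4
        repaired, ok = repair_centers(stack, gap)
        assert ok
        assert np.array_equal(repaired[:, 1], [18, 26, 34, 42, 50, 58])

    def test_band_rows_survive_masking(self):
        """For dmax=16 the kept band is y in [40.4, 43.6] -> rows 41..43."""
        stack = self.build_shifted_stack()
        gap = gap_check(extract_maxima(stack))
        csum = stack.sum(axis=0)
        ys = np.arange(64.0)
        keep = (ys >= 34 + 0.4 * 16) & (ys <= 50 - 0.4 * 16)
        assert np.flatnonzero(keep).tolist() == [41, 42, 43]
        repaired, _ = repair_centers(stack, gap)
        assert repaired[3, 1] in (41, 42, 43)

    def test_unflagged_input_rejected(self):
        pts = np.array([(32, 10), (32, 18), (32, 26), (32, 34), (32, 42), (32, 50)], dtype=float)
        stack = stack_with_peaks([tuple(p) for p in pts])
        with pytest.raises(ValueError, match="flagged"):
            repair_centers(stack, gap_check(pts))

    def test_empty_band_abandons_repair(self):
        ys = [10, 18, 26, 34, 50, 58]
        stack = np.zeros((6, 64, 64))
        for k, y in enumerate(ys):
            stack[k, y, 32] = 1.0  # delta peaks: no mass inside the band
        gap = gap_check(extract_maxima(stack))
        with pytest.warns(UserWarning, match="abandoned"):
            repaired, ok = repair_centers(stack, gap)
        assert not ok
        assert np.array_equal(repaired, gap.maxima)


class TestCropSizes:
    def test_worked_example(self):
        centers = np.array([(50, 100), (50, 164), (50, 232), (50, 304), (50, 380), (50, 470)], dtype=float)
        assert np.allclose(crop_sizes(centers), [96, 99, 105, 111, 114, 114])

    def test_uniform_spacing(self):
        centers = np.stack([np.full(6, 30.0), 100 + 70 * np.arange(6.0)], axis=1)
        assert np.allclose(crop_sizes(centers), 1.5 * 70)

    def test_homogeneity_and_x_invariance(self, rng):
        y = np.sort(rng.uniform(50, 600, 6))
        c1 = np.stack([rng.uniform(0, 100, 6), y], axis=1)
        c2 = np.stack([rng.uniform(0, 100, 6), 2.5 * y], axis=1)
        assert np.allclose(crop_sizes(c2), 2.5 * crop_sizes(c1))

    def test_zero_gap_rejected(self):
        centers = np.array([(0, 10), (0, 10), (0, 30), (0, 40), (0, 50), (0, 60)], dtype=float)
        with pytest.raises(ValueError):
            crop_sizes(centers)


class TestCropVertebra:
    def test_round_trip_within_half_pixel(self, sample):
        side = 128.0
        spec = CropSpec(center=(200.0, 300.0), side=side)
        crop, t = crop_vertebra(sample.pixels, spec, blur_sigma=0)
        assert crop.shape == (256, 256)
        assert t.scale == pytest.approx(0.5)  # 128 / 256
        lm = np.array([[190.0, 280.0], [230.0, 330.0]])
        back = t.apply(t.invert().apply(lm))
        assert np.abs(back - lm).max() < 1e-9
        # crop pixel 128 (the middle) maps exactly onto the window center,
        # crop pixel 0 onto the window's top-left corner
        assert np.allclose(t.apply(np.array([[128.0, 128.0]])), [[200.0, 300.0]])
        assert np.allclose(t.apply(np.array([[0.0, 0.0]])), [[200 - 64, 300 - 64]])

    def test_window_inside_raster_has_no_zero_fill(self, clean_spec):
        from spinemark import generate_phantom

        s = generate_phantom(clean_spec, 3)
        spec = CropSpec(center=(250.0, 300.0), side=100.0)
        crop, _ = crop_vertebra(s.pixels + 10.0, spec, blur_sigma=0)
        assert crop.min() > 0  # background is 100, never zero-filled

    def test_out_of_raster_center_rejected(self, sample):
        with pytest.raises(ValueError):
            crop_vertebra(sample.pixels, CropSpec(center=(-5.0, 10.0), side=50.0))

    def test_content_matches_source(self, sample):
        """Crop at scale 1 reproduces the source pixels exactly."""
        spec = CropSpec(center=(200.0, 300.0), side=256.0)
        crop, t = crop_vertebra(sample.pixels, spec, blur_sigma=0)
        assert t.scale == 1.0
        sub = sample.pixels[300 - 128 : 300 + 128, 200 - 128 : 200 + 128]
        assert np.abs(crop - sub).max() < 1e-9
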