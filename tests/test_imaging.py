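"""Imaging pipeline: grayscale conversion, rasterization, masked histograms."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chromentropy.errors import EmptyROIError, InvalidPolygonError, UnsupportedImageError
from chromentropy.imaging import (
    PixelMask,
    PolygonROI,
    RasterImage,
    compute_roi_entropy,
    rasterize_polygon,
    roi_histogram,
    to_grayscale,
)

from _oracles import pixel_entropy_oracle, rasterize_oracle


def _rgb(*pixels):
    return RasterImage(np.array([list(pixels)], dtype=np.uint8))


class TestGrayscale:
    @pytest.mark.parametrize(
        "pixel, method, expected",
        [
            ((255, 255, 255), "unweighted_mean", 255),  # white fixed point
            ((255, 255, 255), "luma_bt601", 255),
            ((0, 0, 0), "unweighted_mean", 0),
            ((10, 20, 40), "unweighted_mean", 23),      # round(70/3)
            ((100, 200, 50), "luma_bt601", 153),        # round(29.9+117.4+5.7)
            ((1, 0, 0), "unweighted_mean", 0),          # 1/3 rounds down
            ((1, 1, 0), "unweighted_mean", 1),          # 2/3 rounds up
        ],
    )
    def test_pixel_arithmetic(self, pixel, method, expected):
        gray = to_grayscale(_rgb(pixel), method)
        assert gray.pixels[0, 0] == expected

    def test_half_rounds_away_from_zero(self):
        # (0+1+2)/3 = 1 exactly; (1+2+3)/3 = 2; (0+0+1)/3 = 0.33 -> 0;
        # mean 127.5 must round to 128, not 127
        gray = to_grayscale(_rgb((127, 127, 128)), "unweighted_mean")
        assert gray.pixels[0, 0] == round(382 / 3)
        gray = to_grayscale(_rgb((127, 128, 127)), "luma_bt601")
        assert gray.pixels[0, 0] == int(0.299 * 127 + 0.587 * 128 + 0.114 * 127 + 0.5)

    def test_one_channel_input_is_identity_for_both_methods(self, rng):
        img = RasterImage(rng.integers(0, 256, size=(5, 7), dtype=np.uint8))
        for method in ("unweighted_mean", "luma_bt601"):
            out = to_grayscale(img, method)
            np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_rejects_unsupported_inputs(self, rng):
        with pytest.raises(UnsupportedImageError):
            RasterImage(rng.integers(0, 256, size=(4, 4, 2), dtype=np.uint8))
        with pytest.raises(UnsupportedImageError):
            RasterImage(rng.integers(0, 65536, size=(4, 4), dtype=np.uint16))
        with pytest.raises(ValueError):
            to_grayscale(RasterImage(np.zeros((2, 2), dtype=np.uint8)), "nonsense")


@st.composite
def random_polygons(draw, max_coord=64.0):
    n = draw(st.integers(min_value=3, max_value=8))
    coord = st.floats(min_value=-4.0, max_value=max_coord + 4.0)
    verts = draw(
        st.lists(st.tuples(coord, coord), min_size=n, max_size=n).filter(
            lambda vs: abs(_shoelace(vs)) > 1.0
        )
    )
    return PolygonROI(tuple(verts))


def _shoelace(vs):
    s = 0.0
    for i in range(len(vs)):
        x1, y1 = vs[i]
        x2, y2 = vs[(i + 1) % len(vs)]
        s += x1 * y2 - x2 * y1
    return 0.5 * s


class TestRasterizePolygon:
    def test_axis_aligned_square_pixel_count(self):
        roi = PolygonROI(((0, 0), (10, 0), (10, 10), (0, 10)))
        assert rasterize_polygon(roi, 20, 20).n_inside == 100

    def test_right_triangle_pixel_count(self):
        roi = PolygonROI(((0, 0), (4, 0), (0, 4)))
        assert rasterize_polygon(roi, 8, 8).n_inside == 6

    def test_mask_clipped_to_frame(self):
        roi = PolygonROI(((-10, -10), (30, -10), (30, 30), (-10, 30)))
        mask = rasterize_polygon(roi, 8, 8)
        assert mask.n_inside == 64

    def test_polygon_entirely_outside_gives_empty_mask(self):
        roi = PolygonROI(((100, 100), (110, 100), (110, 110), (100, 110)))
        assert rasterize_polygon(roi, 8, 8).n_inside == 0

    @given(random_polygons())
    def test_matches_ray_casting_oracle(self, roi):
        mask = rasterize_polygon(roi, 32, 32)
        oracle = np.array(rasterize_oracle(roi.vertices, 32, 32))
        np.testing.assert_array_equal(mask.inside, oracle)

    def test_self_intersecting_polygon_follows_even_odd_rule(self):
        # bow-tie: the crossing region is traversed twice -> excluded
        roi = PolygonROI(((0, 0), (8, 8), (8, 0), (0, 8)))
        mask = rasterize_polygon(roi, 8, 8)
        oracle = np.array(rasterize_oracle(roi.vertices, 8, 8))
        np.testing.assert_array_equal(mask.inside, oracle)
        # even-odd excludes neither lobe, but covers less than the convex hull
        assert 0 < mask.n_inside < 64

    def test_convex_area_discretization_bound(self, rng):
        for _ in range(10):
            cx, cy = rng.uniform(10, 22, size=2)
            r = rng.uniform(3, 8)
            angles = np.sort(rng.uniform(0, 2 * np.pi, size=12))
            verts = tuple((cx + r * np.cos(a), cy + r * np.sin(a)) for a in angles)
            roi = PolygonROI(verts)
            mask = rasterize_polygon(roi, 32, 32)
            perimeter = sum(
                np.hypot(verts[i][0] - verts[(i + 1) % 12][0],
                         verts[i][1] - verts[(i + 1) % 12][1])
                for i in range(12)
            )
            assert abs(mask.n_inside - roi.area) <= perimeter

    def test_degenerate_polygons_rejected(self):
        with pytest.raises(InvalidPolygonError):
            PolygonROI(((0, 0), (1, 1)))
        with pytest.raises(InvalidPolygonError):
            PolygonROI(((0, 0), (1, 1), (2, 2)))


class TestRoiHistogram:
    def test_constant_region(self):
        gray = RasterImage(np.full((20, 20), 128, dtype=np.uint8))
        mask = rasterize_polygon(PolygonROI(((0, 0), (10, 0), (10, 10), (0, 10))), 20, 20)
        hist = roi_histogram(gray, mask)
        assert hist.counts[128] == 100
        assert hist.total_pixels == 100

    def test_full_frame_mask_totals_all_pixels(self, rng):
        gray = RasterImage(rng.integers(0, 256, size=(16, 16), dtype=np.uint8))
        mask = PixelMask(np.ones((16, 16), dtype=bool))
        assert roi_histogram(gray, mask).total_pixels == 256

    def test_matches_per_pixel_tally(self, rng):
        gray = RasterImage(rng.integers(0, 256, size=(16, 16), dtype=np.uint8))
        mask = PixelMask(rng.random((16, 16)) < 0.5)
        hist = roi_histogram(gray, mask)
        expected = np.zeros(256, dtype=np.int64)
        for r in range(16):
            for c in range(16):
                if mask.inside[r, c]:
                    expected[gray.pixels[r, c]] += 1
        np.testing.assert_array_equal(hist.counts, expected)

    def test_histogram_conservation(self, rng):
        gray = RasterImage(rng.integers(0, 256, size=(16, 16), dtype=np.uint8))
        mask = PixelMask(rng.random((16, 16)) < 0.3)
        if mask.n_inside:
            assert roi_histogram(gray, mask).total_pixels == mask.n_inside

    def test_empty_mask_and_dim_mismatch_are_errors(self, rng):
        gray = RasterImage(rng.integers(0, 256, size=(8, 8), dtype=np.uint8))
        with pytest.raises(EmptyROIError):
            roi_histogram(gray, PixelMask(np.zeros((8, 8), dtype=bool)))
        with pytest.raises(ValueError):
            roi_histogram(gray, PixelMask(np.ones((4, 4), dtype=bool)))


class TestComputeRoiEntropy:
    SQUARE = PolygonROI(((1, 1), (7, 1), (7, 7), (1, 7)), name="sq")

    def test_constant_image_has_zero_entropy(self):
        img = RasterImage(np.full((8, 8, 3), 77, dtype=np.uint8))
        res = compute_roi_entropy(img, self.SQUARE, label="flat")
        assert res.h_bits == 0.0
        assert res.label == "flat"
        assert res.roi_pixels == 36

    def test_two_level_equipartition_is_one_bit(self):
        px = np.zeros((8, 8), dtype=np.uint8)
        px[:, ::2] = 10
        px[:, 1::2] = 200
        res = compute_roi_entropy(RasterImage(px), self.SQUARE)
        assert res.h_bits == pytest.approx(1.0, abs=1e-12)

    def test_provenance_recorded(self, rng):
        img = RasterImage(rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8))
        res = compute_roi_entropy(img, self.SQUARE, method="luma_bt601")
        assert res.grayscale_method == "luma_bt601"
        assert res.bins == 256

    def test_translation_covariance(self, rng):
        px = rng.integers(0, 256, size=(12, 12), dtype=np.uint8)
        big = np.zeros((24, 24), dtype=np.uint8)
        big[:12, :12] = px
        shifted = np.zeros((24, 24), dtype=np.uint8)
        shifted[5:17, 7:19] = px
        roi = PolygonROI(((1, 1), (11, 1), (11, 11), (1, 11)))
        h0 = compute_roi_entropy(RasterImage(big), roi).h_bits
        h1 = compute_roi_entropy(RasterImage(shifted), roi.translated(7, 5)).h_bits
        assert h0 == h1

    def test_histogram_path_equals_pixel_oracle(self, rng):
        """Entropy via histogram pipeline == direct per-pixel frequency tally."""
        for _ in range(20):
            h = int(rng.integers(4, 33))
            w = int(rng.integers(4, 33))
            img = RasterImage(rng.integers(0, 256, size=(h, w), dtype=np.uint8))
            verts = tuple(
                (float(rng.uniform(0, w)), float(rng.uniform(0, h))) for _ in range(5)
            )
            try:
                roi = PolygonROI(verts)
            except InvalidPolygonError:
                continue
            mask = rasterize_polygon(roi, w, h)
            if mask.n_inside == 0:
                continue
            res = compute_roi_entropy(img, roi)
            oracle = pixel_entropy_oracle(img.pixels[mask.inside].tolist())
            assert res.h_bits == pytest.approx(oracle, abs=1e-10)
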