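"""Geometry, normalization and agreement operations of the GSM pipeline."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from carotid_gsm import echogenicity as echo
from carotid_gsm.errors import (
    DegeneratePolygonError,
    EmptyRegionError,
    InsufficientDataError,
    NonDiscriminatingReferencesError,
)

from conftest import brute_force_median3x3, brute_force_point_in_polygon


def _frame(pixels, frame_id="f"):
    return echo.UltrasoundFrame(pixels=np.asarray(pixels, dtype=np.uint8),
                                frame_id=frame_id)


def _annotation(lumen, adventitia, plaque=((1, 1), (5, 1), (5, 5), (1, 5))):
    return echo.AnnotationSet(
        frame_id="f", observer_id="o1",
        plaque_polygon=plaque, lumen_region=lumen, adventitia_region=adventitia,
    )


class TestRasterizePolygon:
    def test_integer_square_area(self):
        mask = echo.rasterize_polygon([(0, 0), (4, 0), (4, 4), (0, 4)], (10, 10))
        assert mask.sum() == 16
        assert mask[:4, :4].all()

    def test_two_vertices_is_degenerate(self):
        with pytest.raises(DegeneratePolygonError):
            echo.rasterize_polygon([(0, 0), (4, 4)], (10, 10))

    def test_polygon_enclosing_no_centers_is_empty(self):
        with pytest.raises(EmptyRegionError):
            echo.rasterize_polygon([(0.1, 0.1), (0.3, 0.1), (0.2, 0.3)], (10, 10))

    @given(st.integers(0, 2**31 - 1))
    def test_random_hexagon_matches_bruteforce_even_odd(self, seed):
        rng = np.random.default_rng(seed)
        verts = rng.uniform(0, 32, size=(6, 2))  # may self-intersect
        try:
            mask = echo.rasterize_polygon(verts, (32, 32))
        except EmptyRegionError:
            mask = np.zeros((32, 32), dtype=bool)
        for r in range(32):
            for c in range(32):
                expected = brute_force_point_in_polygon(c + 0.5, r + 0.5, verts)
                assert mask[r, c] == expected


class TestNormalizeBrightness:
    @pytest.fixture()
    def frame_and_annotation(self):
        # lumen block at rows 0-4 = 40, adventitia rows 10-15 = 160,
        # plaque block rows 5-9 carries the probe values
        px = np.full((16, 16), 100, dtype=np.uint8)
        px[0:5, :] = 40
        px[10:16, :] = 160
        ann = _annotation(
            lumen=[(0, 0), (16, 0), (16, 4.5), (0, 4.5)],
            adventitia=[(0, 10.5), (16, 10.5), (16, 15.5), (0, 15.5)],
            plaque=[(0, 5.5), (16, 5.5), (16, 9.5), (0, 9.5)],
        )
        return px, ann

    @pytest.mark.parametrize(
        "raw,expected",
        [
            (40, 0),      # darkness anchor
            (160, 190),   # brightness anchor
            (100, 95),    # midpoint of the linear map
            (255, 255),   # raw map 190*215/120 = 340.4 -> clipped
        ],
    )
    def test_two_point_map(self, frame_and_annotation, raw, expected):
        px, ann = frame_and_annotation
        px = px.copy()
        px[7, 7] = raw
        normalized = echo.normalize_brightness(_frame(px), ann)
        assert normalized.pixels[7, 7] == expected

    def test_anchor_medians_exact(self, frame_and_annotation):
        px, ann = frame_and_annotation
        normalized = echo.normalize_brightness(_frame(px), ann)
        dims = (16, 16)
        lmask = echo.rasterize_polygon(ann.lumen_region, dims)
        amask = echo.rasterize_polygon(ann.adventitia_region, dims)
        assert np.median(normalized.pixels[lmask]) == 0
        assert np.median(normalized.pixels[amask]) == 190

    def test_non_discriminating_references(self, frame_and_annotation):
        px, ann = frame_and_annotation
        px = px.copy()
        px[0:5, :] = 200  # lumen brighter than adventitia
        with pytest.raises(NonDiscriminatingReferencesError):
            echo.normalize_brightness(_frame(px), ann)

    def test_monotone_outside_clipping(self, frame_and_annotation):
        px, ann = frame_and_annotation
        rng = np.random.default_rng(0)
        px = px.copy()
        px[5:10, :] = rng.integers(41, 160, size=(5, 16))
        normalized = echo.normalize_brightness(_frame(px), ann)
        flat_in = px[5:10, :].ravel().astype(int)
        flat_out = normalized.pixels[5:10, :].ravel().astype(int)
        order = np.argsort(flat_in, kind="stable")
        assert (np.diff(flat_out[order]) >= 0).all()

    def test_idempotent_on_anchored_frame(self, frame_and_annotation):
        px, ann = frame_and_annotation
        px = px.copy()
        px[0:5, :] = 0
        px[10:16, :] = 190
        px[5:10, :] = np.linspace(0, 190, 80).reshape(5, 16).astype(np.uint8)
        normalized = echo.normalize_brightness(_frame(px), ann)
        assert np.array_equal(normalized.pixels, px)


class TestDenoise:
    def test_uniform_unchanged(self):
        out = echo.denoise(_frame(np.full((16, 16), 80)))
        assert (out.pixels == 80).all()

    def test_single_hot_pixel_removed(self):
        px = np.full((16, 16), 50, dtype=np.uint8)
        px[8, 8] = 255
        out = echo.denoise(_frame(px))
        assert out.pixels[8, 8] == 50

    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_median(self, seed):
        rng = np.random.default_rng(seed)
        px = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        out = echo.denoise(_frame(px))
        assert np.array_equal(out.pixels, brute_force_median3x3(px))

    def test_range_never_expands(self):
        rng = np.random.default_rng(5)
        px = rng.integers(30, 200, size=(20, 20)).astype(np.uint8)
        out = echo.denoise(_frame(px))
        assert out.pixels.min() >= px.min() and out.pixels.max() <= px.max()


class TestCropToRoi:
    def test_bounding_box(self):
        px = np.zeros((16, 16), dtype=np.uint8)
        mask = np.zeros((16, 16), dtype=bool)
        mask[3:8, 10:13] = True
        cropped, cmask, offset = echo.crop_to_roi(_frame(px), mask)
        assert cropped.shape == (5, 3) and offset == (3, 10)
        assert cmask.all()

    def test_full_mask_is_identity(self):
        px = np.arange(256, dtype=np.uint8).reshape(16, 16)
        cropped, _, offset = echo.crop_to_roi(_frame(px), np.ones((16, 16), bool))
        assert np.array_equal(cropped, px) and offset == (0, 0)

    def test_empty_mask_errors(self):
        with pytest.raises(EmptyRegionError):
            echo.crop_to_roi(_frame(np.zeros((16, 16))), np.zeros((16, 16), bool))

    @given(st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((16, 16)) < 0.2
        if not mask.any():
            mask[rng.integers(16), rng.integers(16)] = True
        _, _, (r0, c0) = echo.crop_to_roi(_frame(np.zeros((16, 16))), mask)
        rows = [r for r in range(16) for c in range(16) if mask[r, c]]
        cols = [c for r in range(16) for c in range(16) if mask[r, c]]
        assert (r0, c0) == (min(rows), min(cols))


class TestGsmStats:
    def test_uniform_region(self):
        px = np.full((16, 16), 77, dtype=np.uint8)
        res = echo.compute_gsm_stats(_frame(px), np.ones((16, 16), bool))
        assert res.gsm_min == res.gsm_max == res.gsm_mean == res.gsm_median == 77

    def test_even_count_median_is_midpoint(self):
        px = np.zeros((16, 16), dtype=np.uint8)
        mask = np.zeros((16, 16), bool)
        for i, v in enumerate([10, 20, 30, 40]):
            px[0, i] = v
            mask[0, i] = True
        res = echo.compute_gsm_stats(_frame(px), mask)
        assert (res.gsm_min, res.gsm_max, res.gsm_mean, res.gsm_median) == (10, 40, 25, 25)

    def test_empty_mask_errors(self):
        with pytest.raises(EmptyRegionError):
            echo.compute_gsm_stats(_frame(np.zeros((16, 16))), np.zeros((16, 16), bool))

    def test_order_invariants(self):
        rng = np.random.default_rng(7)
        px = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        res = echo.compute_gsm_stats(_frame(px), rng.random((16, 16)) < 0.5)
        assert res.gsm_min <= res.gsm_median <= res.gsm_max
        assert res.gsm_min <= res.gsm_mean <= res.gsm_max


class TestAggregation:
    def _results(self, values, frames=None):
        frames = frames or [f"fr{i}" for i in range(len(values))]
        return [
            echo.EchogenicityResult(frame_id=f, observer_id="o", gsm_min=v,
                                    gsm_max=v, gsm_mean=v, gsm_median=v, n_pixels=10)
            for f, v in zip(frames, values)
        ]

    def test_two_observer_mean(self):
        res = self._results([50, 60], frames=["p1", "p1"])
        assert echo.aggregate_participant("p", res).gsm == 55

    def test_flat_mean(self):
        assert echo.aggregate_participant("p", self._results([40, 60, 80])).gsm == 60

    def test_ten_measurements(self):
        frames = [f"plq{i}" for i in range(5)] * 2
        res = self._results(list(range(1, 11)), frames=frames)
        assert echo.aggregate_participant("p", res).gsm == 5.5

    def test_per_plaque_first_mode(self):
        # plaque A measured 10/30 by two observers, plaque B once at 80
        res = self._results([10, 30, 80], frames=["A", "A", "B"])
        flat = echo.aggregate_participant("p", res)
        nested = echo.aggregate_participant("p", res, per_plaque_first=True)
        assert flat.gsm == 40 and nested.gsm == 50

    def test_empty_errors(self):
        with pytest.raises(InsufficientDataError):
            echo.aggregate_participant("p", [])


class TestSubsample:
    def test_five_percent_of_2700_is_135(self):
        ids = [f"p{i}" for i in range(2700)]
        assert len(echo.interobserver_subsample(ids, 0.05, seed=1)) == 135

    def test_full_fraction_returns_all(self):
        ids = list("abcdef")
        assert sorted(echo.interobserver_subsample(ids, 1.0, seed=2)) == sorted(ids)

    def test_deterministic_under_seed(self):
        ids = [f"p{i}" for i in range(200)]
        assert (echo.interobserver_subsample(ids, 0.05, seed=42)
                == echo.interobserver_subsample(ids, 0.05, seed=42))

    def test_empty_errors(self):
        with pytest.raises(InsufficientDataError):
            echo.interobserver_subsample([], 0.05, seed=0)


class TestAgreement:
    def test_identical_pairs_icc_one(self):
        x = np.array([40.0, 55.0, 60.0, 72.0, 48.0])
        rep = echo.interobserver_agreement(x, x)
        assert rep.icc == pytest.approx(1.0)
        assert rep.mean_difference == 0

    def test_constant_shift(self):
        x = np.array([40.0, 55.0, 60.0, 72.0, 48.0])
        rep = echo.interobserver_agreement(x + 10, x)
        assert rep.mean_difference == pytest.approx(10.0)

    def test_icc_matches_anova_formula(self):
        rng = np.random.default_rng(3)
        truth = rng.normal(55, 12, size=20)
        a = truth + rng.normal(0, 4, 20)
        b = truth + rng.normal(0, 4, 20)
        rep = echo.interobserver_agreement(a, b)

        # two-way ANOVA ICC(2,1), hand evaluation
        n, k = 20, 2
        data = np.column_stack([a, b])
        grand = data.mean()
        msr = k * np.sum((data.mean(axis=1) - grand) ** 2) / (n - 1)
        msc = n * np.sum((data.mean(axis=0) - grand) ** 2) / (k - 1)
        mse = (np.sum((data - data.mean(axis=1, keepdims=True)
                       - data.mean(axis=0, keepdims=True) + grand) ** 2)
               / ((n - 1) * (k - 1)))
        expected = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
        assert rep.icc == pytest.approx(expected, abs=1e-9)

    def test_outlier_flagging(self):
        rng = np.random.default_rng(4)
        x = rng.normal(55, 10, 40)
        y = x + rng.normal(0, 0.5, 40)
        y[13] += 30  # gross disagreement -> remeasurement candidate
        rep = echo.interobserver_agreement(x, y)
        assert 13 in rep.outlier_indices

    def test_single_pair_errors(self):
        with pytest.raises(InsufficientDataError):
            echo.interobserver_agreement([1.0], [1.0])
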