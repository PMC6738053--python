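import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from hypoxvasc.if_quant import (
    classify_caix,
    compute_fcaix,
    determine_threshold,
    filter_small_objects,
    quantify_caix,
    segment_above,
)
from hypoxvasc.images import BinaryImage, RegionMask
from hypoxvasc.synthetic_slides import SlideSimParams, generate_slide

from oracles import flood_components, otsu_bruteforce


class TestDetermineThreshold:
    def test_background_stat_on_constant_image(self, as_channel, full_mask):
        img = as_channel(np.full((10, 10), 7.0))
        thr = determine_threshold(
            img, full_mask((10, 10)), "background", background_mask=full_mask((10, 10))
        )
        assert thr == 7.0  # SD = 0, so mean + 3*SD is the constant itself
        assert segment_above(img, full_mask((10, 10)), thr).n_positive == 0

    def test_bimodal_split_lies_between_modes(self, as_channel, full_mask):
        rng = np.random.default_rng(1)
        arr = np.where(
            rng.uniform(size=(60, 60)) < 0.3,
            rng.normal(1000, 10, (60, 60)),
            rng.normal(100, 10, (60, 60)),
        )
        img = as_channel(np.clip(arr, 0, None))
        thr = determine_threshold(img, full_mask((60, 60)), "otsu")
        assert 100 < thr < 1000
        # independent oracle: exhaustive between-class-variance scan
        oracle = otsu_bruteforce(img.pixels.ravel())
        assert 100 < oracle < 1000
        assert abs(thr - oracle) < 30  # same valley between the two modes

    def test_fixed_value_returned_unchanged(self, as_channel, full_mask):
        img = as_channel(np.zeros((4, 4)))
        assert determine_threshold(img, full_mask((4, 4)), "fixed", value=123.5) == 123.5

    def test_empty_background_mask_errors(self, as_channel, full_mask):
        img = as_channel(np.zeros((4, 4)))
        empty = RegionMask(np.zeros((4, 4), dtype=bool))
        with pytest.raises(ValueError):
            determine_threshold(img, full_mask((4, 4)), "background", background_mask=empty)


class TestSegmentAbove:
    def test_threshold_at_max_gives_empty(self, as_channel, full_mask):
        img = as_channel(np.arange(16.0).reshape(4, 4))
        assert segment_above(img, full_mask((4, 4)), 15.0).n_positive == 0

    def test_threshold_below_all_gives_mask(self, as_channel):
        img = as_channel(np.arange(16.0).reshape(4, 4))
        mask = RegionMask(np.tri(4, dtype=bool))
        out = segment_above(img, mask, -1.0)
        assert np.array_equal(out.positive, mask.include)

    def test_noiseless_slide_recovers_painted_set_exactly(self, small_slide):
        params, (nuclei, caix, vessel, truth) = small_slide
        thr = (params.background_level + params.foreground_level) / 2
        out = segment_above(caix, truth.tumour_mask, thr)
        # speckle rate is 0 in this fixture, so positives == painted pixels
        assert np.array_equal(out.positive, truth.caix_mask)


class TestFilterSmallObjects:
    def test_strict_exceeding_boundary(self):
        grid = np.zeros((10, 10), dtype=bool)
        grid[1, 1:6] = True  # 5-pixel component: removed at min_pixels=5
        out = filter_small_objects(BinaryImage(grid, 0, "hypoxia"), 5)
        assert out.n_positive == 0
        grid6 = np.zeros((10, 10), dtype=bool)
        grid6[1, 1:7] = True  # 6-pixel component: retained
        out6 = filter_small_objects(BinaryImage(grid6, 0, "hypoxia"), 5)
        assert out6.n_positive == 6

    @settings(max_examples=30, deadline=None)
    @given(
        grid=hnp.arrays(bool, (12, 12), elements=st.booleans()),
        min_px=st.integers(0, 8),
    )
    def test_matches_bruteforce_component_enumeration(self, grid, min_px):
        out = filter_small_objects(BinaryImage(grid, 0, "hypoxia"), min_px)
        expected = np.zeros_like(grid)
        for comp in flood_components(grid):
            if len(comp) > min_px:
                for r, c in comp:
                    expected[r, c] = True
        assert np.array_equal(out.positive, expected)

    @settings(max_examples=20, deadline=None)
    @given(grid=hnp.arrays(bool, (12, 12), elements=st.booleans()))
    def test_positive_area_non_increasing_in_min_pixels(self, grid):
        b = BinaryImage(grid, 0, "hypoxia")
        areas = [filter_small_objects(b, m).n_positive for m in range(0, 10)]
        assert all(a >= b_ for a, b_ in zip(areas, areas[1:]))


class TestComputeFcaix:
    def test_ratio_by_construction(self, full_mask):
        grid = np.zeros((100, 100), dtype=bool)
        grid[:5, :100] = True  # 500 positive pixels on a full tumour mask
        res = compute_fcaix(BinaryImage(grid, 0, "hypoxia"), full_mask((100, 100)))
        assert res.fcaix == 0.05

    def test_empty_positive_set(self, full_mask):
        res = compute_fcaix(
            BinaryImage(np.zeros((10, 10), dtype=bool), 0, "hypoxia"), full_mask((10, 10))
        )
        assert res.fcaix == 0.0 and not res.caix_positive

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            compute_fcaix(
                BinaryImage(np.zeros((4, 4), dtype=bool), 0, "hypoxia"),
                RegionMask(np.zeros((4, 4), dtype=bool)),
            )

    def test_mask_monotonicity(self, small_slide):
        params, (nuclei, caix, vessel, truth) = small_slide
        thr = (params.background_level + params.foreground_level) / 2
        binary = segment_above(caix, truth.tumour_mask, thr)
        full = compute_fcaix(binary, truth.tumour_mask)
        shrunk = truth.tumour_mask.include.copy()
        shrunk[::2, :] = False
        res = compute_fcaix(binary, RegionMask(shrunk))
        assert res.positive_pixels <= full.positive_pixels


class TestClassifyCaix:
    @pytest.mark.parametrize(
        "fcaix,expected", [(0.015, True), (0.0, False), (0.01, False), (0.5, True)]
    )
    def test_one_percent_cutoff_is_strict(self, fcaix, expected):
        assert classify_caix(fcaix) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_caix(1.5)


class TestEndToEndRecovery:
    @pytest.mark.parametrize("truth_frac", [0.0, 0.05, 0.3])
    def test_fcaix_within_one_percent_of_truth(self, truth_frac):
        params = SlideSimParams(
            image_shape=(256, 256),
            true_caix_fraction=truth_frac,
            n_vessels=5,
            seed=int(truth_frac * 1000) + 3,
        )
        _, caix, _, truth = generate_slide(params)
        res = quantify_caix(
            caix,
            truth.tumour_mask,
            threshold_method="fixed",
            fixed_value=(params.background_level + params.foreground_level) / 2,
        )
        assert abs(res.fcaix - truth.true_caix_fraction) <= 0.01
        if abs(truth.true_caix_fraction - 0.01) > 0.005:
            assert res.caix_positive == (truth.true_caix_fraction > 0.01)
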