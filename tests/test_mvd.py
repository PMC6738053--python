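import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from hypoxvasc.images import BinaryImage, RegionMask
from hypoxvasc.mvd import (
    HotspotField,
    VesselObject,
    compute_mvd,
    count_in_frame,
    dichotomize_over_median,
    field_size_pixels,
    find_hotspots,
    label_vessels,
)
from hypoxvasc.synthetic_slides import HotspotSpec, SlideSimParams, generate_slide

from oracles import flood_components, frame_classify


def _objects_from_grid(grid):
    return label_vessels(BinaryImage(grid, 0, "vessel"), min_pixels=0)


class TestLabelVessels:
    def test_empty_image(self):
        assert label_vessels(BinaryImage(np.zeros((8, 8), dtype=bool), 0, "vessel")) == []

    def test_strict_two_pixel_exclusion(self):
        grid = np.zeros((8, 8), dtype=bool)
        grid[1, 1:3] = True  # 2-pixel blob: dropped
        grid[5, 1:4] = True  # 3-pixel blob: kept
        objs = label_vessels(BinaryImage(grid, 0, "vessel"), min_pixels=2)
        assert len(objs) == 1 and objs[0].area == 3

    @settings(max_examples=25, deadline=None)
    @given(
        grid=hnp.arrays(bool, (14, 14), elements=st.booleans()),
        min_px=st.integers(0, 4),
    )
    def test_matches_bruteforce_flood_fill(self, grid, min_px):
        objs = label_vessels(BinaryImage(grid, 0, "vessel"), min_pixels=min_px)
        expected = sorted(
            frozenset(c) for c in flood_components(grid) if len(c) > min_px
        )
        got = sorted(
            frozenset(zip(o.rows.tolist(), o.cols.tolist())) for o in objs
        )
        assert got == expected


class TestCountInFrame:
    def test_fully_interior_object_counted(self):
        grid = np.zeros((20, 20), dtype=bool)
        grid[5:8, 5:8] = True
        objs = _objects_from_grid(grid)
        field = HotspotField((2, 2), (10, 10), 0)
        n, counted, excluded = count_in_frame(objs, field)
        assert n == 1 and excluded == []

    def test_left_edge_straddler_counted_right_edge_excluded(self):
        grid = np.zeros((20, 20), dtype=bool)
        grid[5, 0:4] = True  # straddles left edge of field starting at col 2
        grid[10, 8:14] = True  # crosses right edge (cols 8..13 vs field cols 2..11)
        objs = _objects_from_grid(grid)
        field = HotspotField((2, 2), (10, 10), 0)
        n, counted, excluded = count_in_frame(objs, field)
        assert n == 1
        assert len(excluded) == 1

    @settings(max_examples=25, deadline=None)
    @given(
        grid=hnp.arrays(bool, (64, 64), elements=st.booleans()),
        origin=st.tuples(st.integers(0, 40), st.integers(0, 40)),
        size=st.tuples(st.integers(4, 24), st.integers(4, 24)),
    )
    def test_matches_per_pixel_edge_classifier(self, grid, origin, size):
        objs = _objects_from_grid(grid)
        field = HotspotField(origin, size, 0)
        n, counted, excluded = count_in_frame(objs, field)
        comps = {
            o.id: set(zip(o.rows.tolist(), o.cols.tolist())) for o in objs
        }
        expect_counted = [
            i for i, c in comps.items() if frame_classify(c, origin, size) == "counted"
        ]
        expect_excluded = [
            i for i, c in comps.items() if frame_classify(c, origin, size) == "excluded"
        ]
        assert sorted(counted) == sorted(expect_counted)
        assert sorted(excluded) == sorted(expect_excluded)
        # a counted object's bounding box always meets the field
        for i in counted:
            rs = [r for r, _ in comps[i]]
            cs = [c for _, c in comps[i]]
            assert max(rs) >= origin[0] and max(cs) >= origin[1]

    def test_tiling_counts_each_blob_exactly_once(self):
        # compact elliptical blobs from the generator; fields tile the frame
        params = SlideSimParams(
            image_shape=(192, 192),
            tumour_mask_fraction=1.0,
            true_caix_fraction=0.0,
            n_vessels=30,
            vessel_size_range=(6, 30),
            noise_speckle_rate=0.0,
            noise_sigma=0.0,
            seed=11,
        )
        _, _, _, truth = generate_slide(params)
        objs = list(truth.vessel_objects)
        tile = 48
        total = 0
        for r0 in range(0, 192, tile):
            for c0 in range(0, 192, tile):
                n, _, _ = count_in_frame(objs, HotspotField((r0, c0), (tile, tile), 0))
                total += n
        assert total == len(objs)


class TestFindHotspots:
    def test_three_planted_clusters_recovered(self):
        params = SlideSimParams(
            image_shape=(200, 200),
            tumour_mask_fraction=1.0,
            true_caix_fraction=0.0,
            n_vessels=0,
            hotspot_spec=[
                HotspotSpec((40, 40), 18, 6),
                HotspotSpec((40, 160), 18, 5),
                HotspotSpec((160, 100), 18, 4),
            ],
            noise_speckle_rate=0.0,
            noise_sigma=0.0,
            seed=5,
        )
        _, _, _, truth = generate_slide(params)
        objs = list(truth.vessel_objects)
        fields = find_hotspots(objs, (200, 200), (60, 60), k=3, stride=1)
        counts = sorted((f.vessel_count for f in fields), reverse=True)
        assert counts == sorted(truth.per_region_vessel_counts.values(), reverse=True)

    def test_zero_vessels_tie_break_is_lexicographic(self):
        fields = find_hotspots([], (30, 30), (10, 10), k=3, stride=1)
        assert [f.origin for f in fields] == [(0, 0), (0, 10), (0, 20)]
        assert all(f.vessel_count == 0 for f in fields)

    def test_k1_equals_exhaustive_maximum(self):
        rng = np.random.default_rng(7)
        grid = rng.uniform(size=(40, 40)) < 0.04
        objs = _objects_from_grid(grid)
        best = find_hotspots(objs, (40, 40), (12, 12), k=1, stride=1)[0]
        exhaustive = max(
            count_in_frame(objs, HotspotField((r, c), (12, 12), 0))[0]
            for r in range(29)
            for c in range(29)
        )
        assert best.vessel_count == exhaustive

    def test_image_smaller_than_field_errors(self):
        with pytest.raises(ValueError, match="smaller"):
            find_hotspots([], (8, 8), (10, 10))

    def test_mask_restricts_field_centres(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[:, 15:] = True  # centres allowed only in the right half
        fields = find_hotspots([], (30, 30), (10, 10), k=2, mask=RegionMask(mask), stride=1)
        for f in fields:
            assert f.origin[1] + 5 >= 15


class TestComputeMvd:
    def _fields(self, counts):
        return [
            HotspotField((0, 10 * i), (5, 5), c, tuple(range(c))) for i, c in enumerate(counts)
        ]

    def test_mean_of_three_counts(self):
        assert compute_mvd(self._fields([10, 8, 6])).mvd == 8.0

    @pytest.mark.parametrize("summary", ["mean", "max", "sum"])
    def test_constant_counts_invariant_under_mean_max(self, summary):
        expected = {"mean": 7.0, "max": 7.0, "sum": 21.0}[summary]
        assert compute_mvd(self._fields([7, 7, 7]), summary=summary).mvd == expected

    def test_wrong_field_count_errors(self):
        with pytest.raises(ValueError, match="expected 3"):
            compute_mvd(self._fields([1, 2]))


class TestDichotomize:
    def test_median_midpoint_for_even_n(self):
        labels = dichotomize_over_median([1, 2, 3, 4])
        assert labels.tolist() == [False, False, True, True]

    def test_all_equal_gives_all_low(self):
        assert not dichotomize_over_median([5, 5, 5, 5]).any()

    def test_at_most_half_high_and_permutation_invariant(self):
        rng = np.random.default_rng(0)
        vals = rng.poisson(20, size=385).astype(float)
        labels = dichotomize_over_median(vals)
        assert labels.sum() <= len(vals) // 2
        perm = rng.permutation(len(vals))
        labels_perm = dichotomize_over_median(vals[perm])
        assert np.array_equal(labels_perm, labels[perm])
        # sorting oracle: median = central order statistic for odd n
        s = np.sort(vals)
        assert np.array_equal(labels, vals > s[len(vals) // 2])

    def test_fewer_than_two_values_errors(self):
        with pytest.raises(ValueError):
            dichotomize_over_median([3.0])


def test_field_size_from_physical_area():
    rows, cols = field_size_pixels(0.74, 4.0)
    assert rows == cols == round(np.sqrt(0.74) * 1000 / 4.0)
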