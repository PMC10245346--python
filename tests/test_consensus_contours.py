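import numpy as np
import pytest

from crowdvol.consensus_contours import (
    ClosedLoop,
    ClosureReject,
    close_polyline,
    compare_to_expert,
    cria_consensus,
    extract_consensus_contours,
    height_map,
    mask_iou,
    rasterize_interior,
    rasterize_loops,
    remove_outlier_annotations,
)

SQUARE = np.array([[0, 0], [2, 0], [2, 2], [0, 2], [0, 0]], float)


def point_in_polygon_oracle(x, y, vertices):
    """Scalar even-odd ray cast, written independently of the implementation."""
    inside = False
    v = np.asarray(vertices, float)
    for (x1, y1), (x2, y2) in zip(v[:-1], v[1:]):
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


def raster_oracle(vertices, width, height):
    return np.array(
        [
            [point_in_polygon_oracle(i + 0.5, j + 0.5, vertices) for i in range(width)]
            for j in range(height)
        ]
    )


class TestClosePolyline:
    def test_already_closed_square_unchanged(self):
        loop = close_polyline(SQUARE, gap_tolerance=5)
        assert isinstance(loop, ClosedLoop)
        np.testing.assert_array_equal(loop.vertices, SQUARE)

    def test_small_gap_closed_by_appending_first_vertex(self):
        open_square = SQUARE[:-1]  # ends at (0, 2): a 2 px gap back to the start
        loop = close_polyline(open_square, gap_tolerance=5)
        assert isinstance(loop, ClosedLoop)
        assert len(loop.vertices) == len(open_square) + 1
        np.testing.assert_array_equal(loop.vertices[-1], loop.vertices[0])

    def test_large_gap_rejected_with_reason(self):
        line = np.array([[0, 0], [10, 0], [10, 10]], float)
        result = close_polyline(line, gap_tolerance=3)
        assert isinstance(result, ClosureReject) and "gap" in result.reason

    def test_two_point_stroke_rejected(self):
        assert isinstance(close_polyline(np.array([[0, 0], [5, 5]], float), 100), ClosureReject)


class TestRasterize:
    def test_unit_square_exact_pixels(self):
        mask = rasterize_interior(ClosedLoop(SQUARE), 4, 4)
        expected = np.zeros((4, 4), bool)
        expected[:2, :2] = True
        np.testing.assert_array_equal(mask, expected)

    def test_zero_area_loop_empty(self):
        collinear = np.array([[1, 1], [3, 1], [2, 1], [1, 1]], float)
        assert not rasterize_interior(ClosedLoop(collinear), 6, 6).any()

    def test_concave_polygon_matches_oracle(self):
        ell = np.array([[0, 0], [6, 0], [6, 2], [2, 2], [2, 6], [0, 6], [0, 0]], float)
        mask = rasterize_interior(ClosedLoop(ell), 8, 8)
        np.testing.assert_array_equal(mask, raster_oracle(ell, 8, 8))

    def test_self_intersecting_stroke_even_odd(self):
        bowtie = np.array([[0, 0], [6, 6], [6, 0], [0, 6], [0, 0]], float)
        mask = rasterize_interior(ClosedLoop(bowtie), 8, 8)
        np.testing.assert_array_equal(mask, raster_oracle(bowtie, 8, 8))

    def test_random_polygons_match_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            pts = rng.uniform(0.0, 16.0, size=(n, 2))
            poly = np.vstack([pts, pts[:1]])
            mask = rasterize_interior(ClosedLoop(poly), 16, 16)
            np.testing.assert_array_equal(mask, raster_oracle(poly, 16, 16))


class TestHeightMapAndConsensus:
    def _square_mask(self, lo, hi, size=12):
        m = np.zeros((size, size), bool)
        m[lo:hi, lo:hi] = True
        return m

    def test_disjoint_masks_heights_01(self):
        h, n = height_map([self._square_mask(0, 3), self._square_mask(6, 9)])
        assert set(np.unique(h)) <= {0, 1} and n == 2

    def test_nested_masks_form_rings(self):
        masks = [self._square_mask(0, 12), self._square_mask(2, 10), self._square_mask(4, 8)]
        h, _ = height_map(masks)
        assert h[0, 0] == 1 and h[2, 2] == 2 and h[5, 5] == 3

    def test_identical_masks(self):
        m = self._square_mask(2, 8)
        h, n = height_map([m] * 4)
        assert (h[m] == 4).all() and (h[~m] == 0).all()

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            height_map([np.zeros((4, 4), bool), np.zeros((5, 4), bool)])

    def test_single_annotation_is_its_own_consensus(self):
        m = self._square_mask(2, 8)
        c = cria_consensus([m])
        np.testing.assert_array_equal(c.mask, m)
        assert (c.agreement[m] == 1.0).all()

    def test_three_offset_squares_majority(self):
        masks = [self._square_mask(k, k + 6) for k in (0, 1, 2)]
        c = cria_consensus(masks)
        h, n = height_map(masks)
        np.testing.assert_array_equal(c.mask, h >= 2)  # 2h >= 3 means h >= 2

    def test_even_n_half_is_inclusive_union_for_two(self):
        a, b = self._square_mask(0, 3), self._square_mask(6, 9)
        c = cria_consensus([a, b])
        np.testing.assert_array_equal(c.mask, a | b)

    def test_oracle_equivalence_random_mask_sets(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(1, 10))
            shape = tuple(rng.integers(4, 33, size=2))
            masks = [rng.random(shape) < rng.uniform(0.2, 0.8) for _ in range(n)]
            c = cria_consensus(masks)
            counts = np.sum(masks, axis=0)
            np.testing.assert_array_equal(c.mask, counts >= n / 2)
            np.testing.assert_allclose(c.agreement, counts / n)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        masks = [rng.random((10, 10)) < 0.5 for _ in range(5)]
        base = cria_consensus(masks)
        other = cria_consensus(masks[::-1])
        np.testing.assert_array_equal(base.mask, other.mask)

    def test_consensus_shrinks_as_threshold_rises(self):
        rng = np.random.default_rng(13)
        masks = [rng.random((16, 16)) < 0.5 for _ in range(7)]
        h, n = height_map(masks)
        prev = cria_consensus(masks).mask
        for frac in (0.6, 0.75, 0.9, 1.0):
            cur = h >= frac * n
            assert (cur <= prev).all()
            prev = cur


class TestOutlierRemoval:
    def _square_mask(self, lo, hi, size=16):
        m = np.zeros((size, size), bool)
        m[lo:hi, lo:hi] = True
        return m

    def test_discordant_scribble_excluded(self):
        good = [self._square_mask(4, 10) for _ in range(4)]
        scribble = self._square_mask(13, 15)
        consensus, kept = remove_outlier_annotations(
            good + [scribble], contributor_ids=list("abcde")
        )
        assert consensus.excluded == ("e",)
        assert len(kept) == 4
        np.testing.assert_array_equal(consensus.mask, good[0])

    def test_identical_masks_none_excluded(self):
        masks = [self._square_mask(4, 10)] * 3
        consensus, kept = remove_outlier_annotations(masks)
        assert consensus.excluded == () and len(kept) == 3

    def test_expert_mask_used_as_reference(self):
        expert = self._square_mask(4, 10)
        drifted = [self._square_mask(4, 10), self._square_mask(5, 11), self._square_mask(12, 16)]
        consensus, _ = remove_outlier_annotations(
            drifted, contributor_ids=list("abc"), expert_mask=expert
        )
        assert consensus.excluded == ("c",)

    def test_all_excluded_keeps_all_and_flags(self):
        masks = [self._square_mask(0, 4), self._square_mask(12, 16)]
        consensus, kept = remove_outlier_annotations(masks, iou_cutoff=0.99)
        assert consensus.all_excluded and len(kept) == 2


class TestContourExtraction:
    def test_filled_square_round_trip(self):
        mask = np.zeros((10, 10), bool)
        mask[2:7, 3:8] = True
        loops = extract_consensus_contours(mask)
        assert len(loops) == 1
        np.testing.assert_array_equal(rasterize_loops(loops, 10, 10), mask)

    def test_empty_mask(self):
        assert extract_consensus_contours(np.zeros((5, 5), bool)) == []

    def test_two_components_two_loops(self):
        mask = np.zeros((10, 10), bool)
        mask[1:3, 1:3] = True
        mask[6:9, 6:9] = True
        loops = extract_consensus_contours(mask)
        assert len(loops) == 2
        np.testing.assert_array_equal(rasterize_loops(loops, 10, 10), mask)

    def test_holes_and_random_masks_round_trip(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            mask = rng.random((12, 12)) < rng.uniform(0.2, 0.8)
            loops = extract_consensus_contours(mask)
            np.testing.assert_array_equal(rasterize_loops(loops, 12, 12), mask)


class TestExpertComparison:
    def test_identical(self):
        m = np.ones((4, 4), bool)
        stats = compare_to_expert(m, m)
        assert stats["iou"] == 1.0 and stats["dice"] == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4), bool)
        a[0, 0] = True
        b = np.zeros((4, 4), bool)
        b[3, 3] = True
        stats = compare_to_expert(a, b)
        assert stats["iou"] == 0.0 and stats["dice"] == 0.0

    def test_rectangle_overlap_arithmetic(self):
        a = np.zeros((5, 5), bool)
        a[0:2, 0:3] = True  # |A| = 6
        b = np.zeros((5, 5), bool)
        b[0:2, 1:4] = True  # |B| = 6, overlap 2x2
        stats = compare_to_expert(a, b)
        assert stats["iou"] == pytest.approx(0.5)
        assert stats["dice"] == pytest.approx(2 / 3)

    def test_empty_vs_empty_defined_as_one(self):
        assert mask_iou(np.zeros((3, 3), bool), np.zeros((3, 3), bool)) == 1.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            compare_to_expert(np.zeros((3, 3), bool), np.zeros((4, 3), bool))
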