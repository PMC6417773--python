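"""Validation metrics: confusion counts, region matching, distances, areas
and Bland-Altman agreement, each against an independent oracle."""

import numpy as np
import pytest

import octseg as o
from octseg.core import StrutRegion, StrutRegionSet


def _brute_pixel_confusion(a, b):
    tp = fp = fn = tn = 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            if a[i, j] and b[i, j]:
                tp += 1
            elif a[i, j]:
                fp += 1
            elif b[i, j]:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


class TestPixelConfusion:
    def test_identical_masks(self):
        m = np.zeros((10, 10), bool)
        m[2:5, 2:5] = True
        c = o.pixel_confusion(m, m)
        assert (c.tp, c.fp, c.fn) == (9, 0, 0)

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[:2, :2] = True   # area 4
        b[5:8, 5:8] = True  # area 9
        c = o.pixel_confusion(a, b)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 4, 9, 100 - 13)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((32, 32)) < 0.3
        b = rng.random((32, 32)) < 0.3
        c = o.pixel_confusion(a, b)
        assert (c.tp, c.fp, c.fn, c.tn) == _brute_pixel_confusion(a, b)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            o.pixel_confusion(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


class TestSimilarityIndexes:
    def test_basic_arithmetic(self):
        idx = o.similarity_indexes(o.ConfusionCounts(tp=3, fp=0, fn=1, tn=6))
        assert idx.sensitivity == pytest.approx(0.75)
        assert idx.specificity == pytest.approx(1.0)

    def test_zero_denominator_flagged_not_zeroed(self):
        with pytest.warns(UserWarning, match="precision undefined"):
            idx = o.similarity_indexes(o.ConfusionCounts(tp=0, fp=0, fn=2,
                                                         tn=5))
        assert idx.precision is None

    def test_region_counts_have_no_specificity(self):
        idx = o.similarity_indexes(o.ConfusionCounts(tp=3, fp=1, fn=1))
        assert idx.specificity is None
        for v in (idx.sensitivity, idx.precision):
            assert 0.0 <= v <= 1.0


def _square(r0, c0, side=3):
    rr, cc = np.mgrid[r0:r0 + side, c0:c0 + side]
    return StrutRegion(coords=np.column_stack([rr.ravel(), cc.ravel()]))


def _brute_region_match(auto, ref):
    a_sets = [set(map(tuple, r.coords)) for r in auto]
    r_sets = [set(map(tuple, r.coords)) for r in ref]
    tp = sum(1 for a in a_sets if any(a & r for r in r_sets))
    fp = len(a_sets) - tp
    fn = sum(1 for r in r_sets if not any(a & r for a in a_sets))
    return tp, fp, fn


class TestRegionMatch:
    def test_identical_sets(self):
        regs = [_square(0, 0), _square(10, 10), _square(20, 0)]
        s = StrutRegionSet(frame_index=0, regions=regs)
        c, pairs = o.region_match(s, s)
        assert (c.tp, c.fp, c.fn) == (3, 0, 0)
        assert sorted(pairs) == [(0, 0), (1, 1), (2, 2)]

    def test_single_pixel_overlap_is_tp(self):
        auto = StrutRegionSet(frame_index=0, regions=[_square(0, 0)])
        ref = StrutRegionSet(frame_index=0, regions=[_square(2, 2)])
        c, pairs = o.region_match(auto, ref)  # overlap exactly (2,2)
        assert c.tp == 1 and pairs == [(0, 0)]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        auto = StrutRegionSet(frame_index=0, regions=[
            _square(rng.integers(0, 30), rng.integers(0, 30),
                    side=rng.integers(2, 5)) for _ in range(3)])
        ref = StrutRegionSet(frame_index=0, regions=[
            _square(rng.integers(0, 30), rng.integers(0, 30),
                    side=rng.integers(2, 5)) for _ in range(5)])
        c, _ = o.region_match(auto, ref)
        assert (c.tp, c.fp, c.fn) == _brute_region_match(auto, ref)

    def test_one_to_one_mode_limits_reuse(self):
        # two auto regions hitting the same reference region
        auto = StrutRegionSet(frame_index=0,
                              regions=[_square(0, 0), _square(2, 2)])
        ref = StrutRegionSet(frame_index=0, regions=[_square(1, 1, side=4)])
        c_def, _ = o.region_match(auto, ref)
        assert (c_def.tp, c_def.fp, c_def.fn) == (2, 0, 0)
        c_121, pairs = o.region_match(auto, ref, one_to_one=True)
        assert (c_121.tp, c_121.fp, c_121.fn) == (1, 1, 0)
        assert len(pairs) == 1


class TestStrutDistances:
    def _pair(self, a_rc, b_rc):
        return (StrutRegion(coords=np.array([a_rc])),
                StrutRegion(coords=np.array([b_rc])))

    def test_coincident_centroids(self):
        total, radial = o.strut_distances([self._pair((50, 50), (50, 50))],
                                          (0, 0))
        assert total[0] == 0 and radial[0] == 0

    def test_collinear_centroids(self):
        # both on the same ray from the centre: radii 100 and 104 px
        total, radial = o.strut_distances([self._pair((100, 0), (104, 0))],
                                          (0, 0), pixel_size_um=15.0)
        assert total[0] == pytest.approx(60.0, abs=1e-9)
        assert radial[0] == pytest.approx(60.0, abs=1e-9)

    def test_equal_radius_chord(self):
        # same radius 100 px, 90 deg apart: chord 100*sqrt(2), radial 0
        total, radial = o.strut_distances([self._pair((100, 0), (0, 100))],
                                          (0, 0), pixel_size_um=15.0)
        assert total[0] == pytest.approx(100 * np.sqrt(2) * 15.0, abs=1e-6)
        assert radial[0] == pytest.approx(0.0, abs=1e-9)

    def test_radial_never_exceeds_total(self, rng):
        pairs = [self._pair(tuple(rng.integers(0, 200, 2)),
                            tuple(rng.integers(0, 200, 2)))
                 for _ in range(50)]
        total, radial = o.strut_distances(pairs, (100, 100))
        assert (radial <= total + 1e-9).all()

    def test_empty_pairs_warn(self):
        with pytest.warns(UserWarning, match="no matched"):
            total, radial = o.strut_distances([], (0, 0))
        assert total.size == 0


class TestContourDistance:
    def test_identical_contours(self):
        cnt = o.LumenContour(radius_px=np.full(360, 50.0), center_rc=(0, 0))
        assert o.contour_distance(cnt, cnt).max() == 0

    def test_constant_offset(self):
        a = o.LumenContour(radius_px=np.full(360, 52.0), center_rc=(0, 0))
        b = o.LumenContour(radius_px=np.full(360, 50.0), center_rc=(0, 0))
        d = o.contour_distance(a, b, pixel_size_um=15.0)
        assert np.allclose(d, 30.0)

    def test_mismatched_grids_resampled_with_warning(self):
        a = o.LumenContour(radius_px=np.full(360, 50.0), center_rc=(0, 0))
        b = o.LumenContour(radius_px=np.full(180, 50.0), center_rc=(0, 0))
        with pytest.warns(UserWarning, match="resampling"):
            d = o.contour_distance(a, b)
        assert np.allclose(d, 0.0)


class TestLumenArea:
    def test_circle_matches_closed_form(self):
        cnt = o.LumenContour(radius_px=np.full(360, 100.0), center_rc=(0, 0))
        area = o.lumen_area(cnt, pixel_size_um=15.0)
        exact = np.pi * 1.5 ** 2
        assert abs(area - exact) / exact < 0.005

    def test_square_contour_exact(self):
        th = np.arange(360) * (2 * np.pi / 360)
        radii = 50.0 / np.maximum(np.abs(np.cos(th)), np.abs(np.sin(th)))
        cnt = o.LumenContour(radius_px=radii, center_rc=(0, 0))
        # vertices lie on the sides of a 100x100 px square => exact area
        assert o.lumen_area(cnt, pixel_size_um=15.0) == pytest.approx(2.25)

    def test_area_scales_quadratically(self):
        a1 = o.lumen_area(o.LumenContour(radius_px=np.full(360, 50.0),
                                         center_rc=(0, 0)))
        a2 = o.lumen_area(o.LumenContour(radius_px=np.full(360, 100.0),
                                         center_rc=(0, 0)))
        assert a2 == pytest.approx(4 * a1)

    def test_self_intersecting_rejected(self):
        bowtie = np.array([[0, 0], [10, 10], [0, 10], [10, 0]], dtype=float)
        with pytest.raises(ValueError, match="self-intersecting"):
            o.lumen_area(bowtie)


class TestAgreement:
    def test_identical_series(self):
        with pytest.warns(UserWarning, match="undefined"):
            s = o.agreement([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert s.bias == 0 and s.loa_low == 0 and s.loa_high == 0
        assert s.r is None

    def test_constant_offset(self):
        a = np.array([5.0, 6.0, 7.0, 8.0])
        s = o.agreement(a, a + 0.5)
        assert s.bias == pytest.approx(-0.5)
        assert s.loa_low == pytest.approx(-0.5)
        assert s.loa_high == pytest.approx(-0.5)
        assert s.r == pytest.approx(1.0)

    def test_six_pairs_match_longhand_computation(self):
        a = np.array([6.1, 5.3, 7.2, 6.8, 5.9, 6.4])
        b = np.array([6.0, 5.6, 7.0, 6.5, 6.2, 6.1])
        d = a - b
        bias = d.sum() / 6
        sd = np.sqrt(((d - bias) ** 2).sum() / 5)
        s = o.agreement(a, b)
        assert s.bias == pytest.approx(bias)
        assert s.loa_low == pytest.approx(bias - 1.96 * sd)
        assert s.loa_high == pytest.approx(bias + 1.96 * sd)
        assert s.loa_low <= s.bias <= s.loa_high

    def test_quartiles_helper(self):
        q1, med, q3 = o.distance_quartiles([1, 2, 3, 4, 5])
        assert (q1, med, q3) == (2, 3, 4)
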