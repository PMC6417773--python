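"""Gamma filtering, core-candidate morphology, rough segmentation, the
reference line, the region of maximum likelihood, and the composed strut
detector."""

import dataclasses

import numpy as np
import pytest

import octseg as o
from octseg.core import StrutRegion, StrutRegionSet
from octseg.stent import likelihood_region, reference_line


class TestGammaFilter:
    def test_fixed_points_any_gamma(self):
        for g in (0.2, 0.6, 1.0):
            px = np.array([[0, 255]], dtype=np.uint8)
            out = o.gamma_filter(px, g)
            assert out[0, 0] == 0 and out[0, 1] == 255

    def test_gamma_one_is_identity(self, rng):
        px = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        assert np.array_equal(o.gamma_filter(px, 1.0), px)

    def test_midtone_value_matches_power_law(self):
        # direct evaluation: 255 * (128/255)**0.6 = 168.63 -> 169
        expected = int(np.floor(255.0 * (128 / 255.0) ** 0.6 + 0.5))
        out = o.gamma_filter(np.array([[128]], dtype=np.uint8), 0.6)
        assert out[0, 0] == expected == 169

    def test_monotone_and_mass_preserving(self, rng):
        px = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        out = o.gamma_filter(px, 0.6)
        # monotone map: ordering of any two intensities is preserved
        lut = o.gamma_filter(np.arange(256, dtype=np.uint8).reshape(1, -1), 0.6)
        assert (np.diff(lut.ravel().astype(int)) >= 0).all()
        assert out.size == px.size  # histogram mass preserved

    def test_rejects_nonpositive_gamma(self):
        with pytest.raises(ValueError):
            o.gamma_filter(np.zeros((2, 2), np.uint8), 0.0)


def _boxed_image(gap_cols=None):
    """24x24 canvas: a solid bright block (keeps the 0.85 quantile at the
    bright level) plus an 8x10 bright box with 1-px rim and 6x8 interior."""
    img = np.zeros((24, 24), dtype=np.uint8)
    img[0:8, 0:8] = 255
    img[12:20, 10:20] = 255
    img[13:19, 11:19] = 0
    if gap_cols is not None:
        img[12, gap_cols] = 0
    interior = np.zeros((24, 24), bool)
    interior[13:19, 11:19] = True
    return img, interior


class TestCoreCandidates:
    def test_closed_box_yields_exact_interior(self):
        img, interior = _boxed_image()
        mask = o.core_candidates(img, o.StentConfig())
        assert np.array_equal(mask, interior)
        assert mask.sum() == 48

    def test_one_pixel_gap_sealed_by_radius1_closing(self):
        img, interior = _boxed_image(gap_cols=slice(15, 16))
        mask = o.core_candidates(img, o.StentConfig())
        assert np.array_equal(mask, interior)

    def test_five_pixel_gap_leaks(self):
        img, interior = _boxed_image(gap_cols=slice(12, 17))
        mask = o.core_candidates(img, o.StentConfig())
        assert not (mask & interior).any()


class TestRoughStruts:
    def _frame_with_interior(self, side):
        img = np.zeros((48, 48), dtype=np.uint8)
        img[0:24, 0:24] = 255  # quantile stabilizer
        lo = 30
        img[lo - 1:lo + side + 1, lo - 1:lo + side + 1] = 255
        img[lo:lo + side, lo:lo + side] = 0
        return o.OctFrame(pixels=img)

    def test_large_interior_survives_opening(self):
        out = o.rough_struts(self._frame_with_interior(12), o.StentConfig())
        assert len(out) == 1
        assert out.provenance == "rough"

    def test_small_interior_removed_by_opening(self):
        out = o.rough_struts(self._frame_with_interior(3), o.StentConfig())
        assert len(out) == 0

    def test_empty_frame_gives_empty_set(self):
        frame = o.OctFrame(pixels=np.zeros((32, 32), np.uint8))
        assert len(o.rough_struts(frame, o.StentConfig())) == 0


class TestAreaFilter:
    @staticmethod
    def _region_of_area(n, offset):
        cols = np.arange(n)
        return StrutRegion(coords=np.column_stack(
            [np.full(n, offset), cols]))

    def test_inclusive_bounds(self):
        areas = [5, 10, 150, 300, 301]
        regions = StrutRegionSet(frame_index=0, regions=[
            self._region_of_area(a, i) for i, a in enumerate(areas)])
        kept = o.area_filter(regions, o.StentConfig())
        assert sorted(r.area_px for r in kept) == [10, 150, 300]

    def test_empty_and_identity(self):
        empty = StrutRegionSet(frame_index=0)
        assert len(o.area_filter(empty, o.StentConfig())) == 0
        inside = StrutRegionSet(frame_index=0, regions=[
            self._region_of_area(a, i) for i, a in enumerate([20, 40])])
        assert len(o.area_filter(inside, o.StentConfig())) == 2

    def test_raising_area_min_never_adds_regions(self, rng):
        areas = rng.integers(1, 400, size=40)
        regions = StrutRegionSet(frame_index=0, regions=[
            self._region_of_area(int(a), i) for i, a in enumerate(areas)])
        prev = len(o.area_filter(regions, o.StentConfig(area_min_px=5)))
        for amin in (20, 50, 150, 299):
            cur = len(o.area_filter(regions, o.StentConfig(area_min_px=amin)))
            assert cur <= prev
            prev = cur


class TestReferenceLine:
    def test_cocircular_centroids_recover_circle(self):
        th = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pts = np.column_stack([100 + 60 * np.sin(th), 100 + 60 * np.cos(th)])
        radii = reference_line(pts, center_rc=(100, 100))
        assert np.abs(radii - 60).max() < 1.0

    def test_pooled_neighbors_alone_define_the_line(self):
        # frame i has no rough struts; its neighbours' centroids still give
        # a radius-60 reference line after pooling
        th = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        neighbour_pts = np.column_stack([100 + 60 * np.sin(th),
                                         100 + 60 * np.cos(th)])
        pooled = np.vstack([np.empty((0, 2)), neighbour_pts])
        radii = reference_line(pooled, center_rc=(100, 100))
        assert np.abs(radii - 60).max() < 1.0

    def test_too_few_centroids_fall_back_to_lumen(self):
        lumen = o.LumenContour(radius_px=np.full(360, 75.0),
                               center_rc=(100, 100))
        pts = [(40.0, 100.0), (100.0, 160.0), (160.0, 100.0)]
        with pytest.warns(UserWarning, match="fewer than 4"):
            radii = reference_line(pts, center_rc=(100, 100), fallback=lumen)
        assert np.allclose(radii, 75.0)

    def test_no_fallback_raises(self):
        with pytest.raises(ValueError, match="fallback"):
            reference_line([(0.0, 1.0)], center_rc=(0, 0))


class TestLikelihoodRegion:
    def _circle_contour(self, radius, center=(100.0, 100.0)):
        return o.LumenContour(radius_px=np.full(360, float(radius)),
                              center_rc=center)

    def test_identical_refline_gives_5px_band(self):
        lumen = self._circle_contour(80)
        mask = likelihood_region(lumen, lumen.radius_px, (200, 200),
                                 o.StentConfig())
        # brute-force point-to-curve distance oracle on a pixel subsample
        pts = lumen.cartesian_points(closed=False)
        rr, cc = np.mgrid[0:200:4, 0:200:4]
        for r, c in zip(rr.ravel(), cc.ravel()):
            d = np.min(np.hypot(pts[:, 0] - r, pts[:, 1] - c))
            if d <= 4.0:
                assert mask[r, c]
            elif d >= 6.5:
                assert not mask[r, c]

    def test_disjoint_bands_give_empty_mask(self):
        lumen = self._circle_contour(60)
        with pytest.warns(UserWarning, match="empty region"):
            mask = likelihood_region(lumen, np.full(360, 120.0), (200, 200),
                                     o.StentConfig())
        assert not mask.any()

    def test_concentric_refline_annulus(self):
        lumen = self._circle_contour(80)
        mask = likelihood_region(lumen, np.full(360, 85.0), (200, 200),
                                 o.StentConfig())
        rr, cc = np.indices((200, 200))
        rad = np.hypot(rr - 100, cc - 100)
        # intersection of [60,100] (lumen band) and [80,90] (refline band)
        assert mask[(rad > 81) & (rad < 89)].all()
        assert not mask[(rad < 78) | (rad > 92)].any()


class TestSegmentStruts:
    def test_clean_phantom_frame_fully_recovered(self, small_spec):
        spec = dataclasses.replace(small_spec, n_frames=1)
        frame, ft = o.generate_frame(spec, 0)
        clean = o.remove_artifacts(frame, o.preprocess_config_for(spec))
        lumen = o.segment_lumen(clean, o.PreprocessConfig(), o.LumenConfig())
        rough = o.rough_struts(clean, o.StentConfig())
        out = o.segment_struts(clean, lumen, rough.centroids_rc,
                               o.StentConfig())
        counts, _ = o.region_match(out, ft.strut_regions)
        assert counts.tp == ft.strut_count
        assert counts.fp == 0 and counts.fn == 0

    def test_decoy_boxes_outside_lumen_band_rejected(self):
        spec = o.PhantomSpec(n_frames=1, seed=5)
        frame, ft = o.generate_frame(spec, 0)
        px = frame.pixels.copy()
        c = (spec.image_size_px - 1) / 2
        # 20 bright closed boxes with dark cores deep inside the wall,
        # > 30 px outside the dilated lumen band
        for k in range(20):
            alpha = 2 * np.pi * (k + 0.5) / 20
            rad = spec.radius_at(alpha, 0) + 55
            cy, cx = int(c + rad * np.sin(alpha)), int(c + rad * np.cos(alpha))
            px[cy - 7:cy + 7, cx - 10:cx + 10] = 255
            px[cy - 5:cy + 5, cx - 8:cx + 8] = 0
        decoyed = o.OctFrame(pixels=px)
        clean = o.remove_artifacts(decoyed, o.preprocess_config_for(spec))
        lumen = o.segment_lumen(clean, o.PreprocessConfig(), o.LumenConfig())
        rough = o.rough_struts(clean, o.StentConfig())
        out = o.segment_struts(clean, lumen, rough.centroids_rc,
                               o.StentConfig())
        counts, _ = o.region_match(out, ft.strut_regions)
        assert counts.fp == 0            # no decoy survives
        assert counts.tp == ft.strut_count

    def test_final_regions_satisfy_contracts(self, small_run):
        cfg = o.StentConfig()
        for seg in small_run:
            for reg in seg.struts:
                assert cfg.area_min_px <= reg.area_px <= cfg.area_max_px
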