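"""Thresholding, component measurement and area-change computation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memfuse import segmentation as seg


def cross_entropy_oracle(image):
    """Brute-force Li-Tam minimiser: full criterion at every candidate split.

    Independent of the vectorised implementation: evaluates the complete
    cross-entropy sum (including the g*log g term) per candidate in a plain
    loop and returns the set of foreground grey values of the best split.
    """
    vals = np.unique(np.asarray(image, dtype=float))
    offset = vals.min() - 1.0
    flat = np.asarray(image, dtype=float).ravel() - offset
    best_eta, best_fg = None, None
    for t in vals[1:] - offset:
        eta = 0.0
        for part in (flat[flat < t], flat[flat >= t]):
            if part.size:
                mu = part.mean()
                eta += float(np.sum(part * np.log(part / mu)))
        if best_eta is None or eta < best_eta - 1e-12:
            best_eta, best_fg = eta, t
    return set(np.round(flat[flat >= best_fg] + offset, 9))


class TestLiThreshold:
    def test_bimodal_partitions_exactly(self):
        img = np.array([10.0] * 192 + [200.0] * 64).reshape(16, 16)
        t = seg.li_threshold(img)
        assert 10 < t <= 200
        assert set(img[img >= t].ravel()) == {200.0}
        assert set(img[img < t].ravel()) == {10.0}

    def test_constant_image_has_no_threshold(self):
        with pytest.raises(ValueError, match="no threshold"):
            seg.li_threshold(np.full((8, 8), 7.0))

    def test_small_image_matches_exhaustive_oracle(self):
        img = np.array(
            [
                [5, 5, 20, 90, 110, 110],
                [5, 20, 20, 90, 90, 110],
                [5, 5, 5, 20, 90, 110],
                [20, 5, 20, 90, 110, 90],
                [5, 20, 5, 20, 90, 110],
                [5, 5, 20, 5, 90, 90],
            ],
            dtype=float,
        )
        t = seg.li_threshold(img)
        fg = set(np.round(img[img >= t].ravel(), 9))
        assert fg == cross_entropy_oracle(img)

    @settings(max_examples=60, deadline=None)
    @given(data=st.data())
    def test_random_images_match_oracle(self, data):
        arr = data.draw(
            st.lists(st.integers(0, 40), min_size=256, max_size=256).map(
                lambda x: np.array(x, dtype=float).reshape(16, 16)
            )
        )
        if np.unique(arr).size < 2:
            return
        t = seg.li_threshold(arr)
        assert set(np.round(arr[arr >= t].ravel(), 9)) == cross_entropy_oracle(arr)

    def test_shift_covariance(self, rng):
        img = rng.integers(0, 255, size=(16, 16)).astype(float)
        for c in (1.0, 37.0, -12.5):
            assert seg.li_threshold(img + c) == pytest.approx(
                seg.li_threshold(img) + c, abs=1e-9
            )

    def test_agrees_with_reference_library_on_bimodal_data(self, rng):
        # independent cross-check: same partition as scikit-image's Li filter
        from skimage.filters import threshold_li

        img = np.concatenate(
            [rng.normal(20, 3, 700), rng.normal(180, 10, 324)]
        ).reshape(32, 32)
        ours = seg.li_threshold(img)
        theirs = threshold_li(img)
        assert np.array_equal(img >= ours, img > theirs)


class TestSegmentPatches:
    def test_single_square_forced_arithmetic(self):
        img = np.zeros((20, 20))
        img[5:15, 5:15] = 100.0
        labels, recs = seg.segment_patches(img, 50.0, pixel_size=0.132)
        assert len(recs) == 1
        assert recs[0].gross_pixels == 100
        assert recs[0].net_area == pytest.approx(1.7424, rel=1e-12)

    def test_gap_separates_patches(self):
        img = np.zeros((20, 30))
        img[5:15, 5:15] = 100.0
        img[5:15, 16:26] = 100.0
        _, recs = seg.segment_patches(img, 50.0, 1.0)
        assert len(recs) == 2

    def test_border_touching_discarded(self):
        img = np.zeros((20, 20))
        img[0:5, 0:5] = 100.0
        img[8:12, 8:12] = 100.0
        _, recs = seg.segment_patches(img, 50.0, 1.0)
        assert len(recs) == 1
        assert recs[0].gross_pixels == 16

    def test_min_size_filter(self):
        img = np.zeros((30, 30))
        img[5:7, 5:7] = 100.0       # 4 px
        img[10:20, 10:20] = 100.0   # 100 px
        _, recs = seg.segment_patches(img, 50.0, 1.0, min_size=10.0)
        assert [r.gross_pixels for r in recs] == [100]

    def test_labels_in_raster_order(self):
        img = np.zeros((30, 30))
        img[20:25, 2:7] = 100.0
        img[2:7, 20:25] = 100.0
        _, recs = seg.segment_patches(img, 50.0, 1.0)
        # the patch whose first pixel comes first in raster order gets id 1
        assert recs[0].patch_id == 1
        assert recs[0].centroid[0] < recs[1].centroid[0]

    def test_enclosed_hole_not_part_of_component(self):
        img = np.zeros((14, 14))
        img[2:12, 2:12] = 100.0
        img[6:8, 6:8] = 0.0
        _, recs = seg.segment_patches(img, 50.0, 1.0)
        assert recs[0].gross_pixels == 96  # hole accounting is measure_patch_area's job


class TestMeasurePatchArea:
    @staticmethod
    def _label_square_with_hole():
        img = np.zeros((28, 28))
        img[4:24, 4:24] = 100.0
        img[10:14, 10:14] = 0.0
        labels, _ = seg.segment_patches(img, 50.0, 1.0)
        return labels

    def test_solid_square_no_holes(self):
        img = np.zeros((20, 20))
        img[5:15, 5:15] = 100.0
        labels, _ = seg.segment_patches(img, 50.0, 1.0)
        rec = seg.measure_patch_area(labels, 1, 1.0)
        assert rec.hole_pixels == 0
        assert rec.net_area == rec.gross_pixels == 100

    def test_enclosed_hole_subtracted(self):
        rec = seg.measure_patch_area(self._label_square_with_hole(), 1, 0.132)
        assert rec.gross_pixels == 400
        assert rec.hole_pixels == 16
        assert rec.net_area == pytest.approx(384 * 0.132**2, rel=1e-12)

    def test_boundary_open_notch_is_not_a_hole(self):
        img = np.zeros((20, 20))
        img[5:15, 5:15] = 100.0
        img[5:10, 9:11] = 0.0  # notch open to the top edge of the square
        labels, _ = seg.segment_patches(img, 50.0, 1.0)
        rec = seg.measure_patch_area(labels, 1, 1.0)
        assert rec.hole_pixels == 0

    def test_unknown_patch_id(self):
        with pytest.raises(ValueError, match="unknown patch_id"):
            seg.measure_patch_area(np.zeros((5, 5), dtype=int), 3, 1.0)

    def test_rotation_robust_disc_area(self):
        rr, cc = np.mgrid[0:41, 0:41]
        disc = ((rr - 20.3) ** 2 + (cc - 20.7) ** 2 <= 13.0**2).astype(float) * 100
        labels, _ = seg.segment_patches(disc, 50.0, 1.0)
        a = seg.measure_patch_area(labels, 1, 1.0).net_area
        labels_rot, _ = seg.segment_patches(np.rot90(disc), 50.0, 1.0)
        assert seg.measure_patch_area(labels_rot, 1, 1.0).net_area == a


class TestMatching:
    @staticmethod
    def _records(img):
        labels, recs = seg.segment_patches(img, 50.0, 1.0)
        return recs

    def test_identity_matching(self):
        img = np.zeros((40, 40))
        img[5:15, 5:15] = 100.0
        img[25:35, 25:35] = 100.0
        recs = self._records(img)
        pairs, ua, ub = seg.match_patches(recs, recs)
        assert len(pairs) == 2 and not ua and not ub
        assert all(a.patch_id == b.patch_id for a, b in pairs)

    def test_translated_patch_still_matched(self):
        img_a = np.zeros((40, 40))
        img_a[5:15, 5:15] = 100.0
        img_a[25:35, 25:35] = 100.0
        img_b = np.zeros((40, 40))
        img_b[5:15, 7:17] = 100.0  # translated 2 px
        img_b[25:35, 25:35] = 100.0
        pairs, ua, ub = seg.match_patches(self._records(img_a), self._records(img_b))
        assert len(pairs) == 2 and not ua and not ub

    def test_disappearing_patch_reported_unmatched(self):
        img_a = np.zeros((40, 40))
        img_a[5:15, 5:15] = 100.0
        img_a[25:35, 25:35] = 100.0
        img_b = np.zeros((40, 40))
        img_b[5:15, 5:15] = 100.0
        pairs, ua, ub = seg.match_patches(self._records(img_a), self._records(img_b))
        assert len(pairs) == 1
        assert len(ua) == 1 and not ub


class TestAreaDilation:
    @staticmethod
    def _rec(n_pixels, pixel_size=1.0, pid=1):
        return seg.PatchAreaRecord(
            patch_id=pid, frame_label="relaxed", gross_pixels=n_pixels,
            hole_pixels=0, pixel_size=pixel_size, centroid=(0.0, 0.0),
            bounding_box=(0, 0, 1, 1),
        )

    @pytest.mark.parametrize(
        "a0,am,expected",
        [(1000, 1000, 0.0), (1000, 1016, 0.016), (1000, 990, -0.010)],
    )
    def test_rel_change(self, a0, am, expected):
        d = seg.compute_area_dilation(self._rec(a0), self._rec(am))
        assert d.rel_change == pytest.approx(expected, rel=1e-12)

    def test_error_propagates_in_quadrature(self):
        d = seg.compute_area_dilation(self._rec(1000), self._rec(1016), 3.0, 4.0)
        assert d.rel_change_err == pytest.approx(5.0 / 1000.0, rel=1e-12)

    def test_zero_initial_area_rejected(self):
        with pytest.raises(ValueError):
            seg.compute_area_dilation(self._rec(0), self._rec(10))

    def test_size_window_bounds_inclusive(self):
        recs = [self._rec(n, pid=i) for i, n in enumerate((50, 100, 900, 7000, 7001))]
        kept = seg.filter_patches(recs)
        assert [r.gross_pixels for r in kept] == [100, 900, 7000]
        assert seg.filter_patches([]) == []
        assert seg.filter_patches(kept) == kept
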