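"""Fusion-efficiency quantification and vesicle-spot handling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memfuse import fusion as fq
from memfuse.simulate import SceneConfig, generate_guv_stack, generate_patch_scene


@pytest.fixture(scope="module")
def planted_scene():
    """Noiseless scene with known docked/hemifused spots and references."""
    cfg = SceneConfig(
        noise=(0.0, 0.0), bleach_rate=0.0, n_patches=1,
        patch_area_range=(900.0, 900.0), image_shape=(512, 512),
        patch_behavior_probs=(1.0, 0.0, 0.0), target_dilations=(0.016,), seed=3,
    )
    return generate_patch_scene(cfg)


class TestEfficiencyFormula:
    @pytest.mark.parametrize(
        "ip,ib,im,expected",
        [(10.0, 10.0, 210.0, 0.0), (210.0, 10.0, 210.0, 100.0), (30.0, 10.0, 210.0, 10.0)],
    )
    def test_worked_values(self, ip, ib, im, expected):
        m = fq.IntensityMeasurement(I_patch=ip, I_back=ib, I_max=im)
        assert fq.fusion_efficiency(m) == pytest.approx(expected, rel=1e-12)

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValueError):
            fq.IntensityMeasurement(I_patch=1.0, I_back=5.0, I_max=5.0)

    def test_negative_values_not_clamped(self):
        m = fq.IntensityMeasurement(I_patch=8.0, I_back=10.0, I_max=210.0)
        assert fq.fusion_efficiency(m) == pytest.approx(-1.0)

    @settings(max_examples=100, deadline=None)
    @given(
        ip=st.floats(0, 500), ib=st.floats(0, 99), im=st.floats(100, 1000),
        gain=st.floats(0.1, 10), offset=st.floats(-50, 50),
    )
    def test_affine_invariance(self, ip, ib, im, gain, offset):
        base = fq.fusion_efficiency(fq.IntensityMeasurement(ip, ib, im))
        moved = fq.fusion_efficiency(
            fq.IntensityMeasurement(gain * ip + offset, gain * ib + offset, gain * im + offset)
        )
        assert moved == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestBackgroundAndReference:
    def test_uniform_background(self):
        img = np.full((100, 100), 100.0)
        masks = np.zeros((100, 100), dtype=int)
        masks[40:60, 40:60] = 1
        img[masks > 0] = 500.0
        assert fq.estimate_background(img, masks) == pytest.approx(100.0)

    def test_stray_bright_spot_excluded_by_median_and_mask(self):
        img = np.full((100, 100), 100.0)
        masks = np.zeros((100, 100), dtype=int)
        masks[40:60, 40:60] = 1
        img[30, 50] = 5000.0  # stray settled vesicle in the annulus
        spot = [fq.VesicleSpot(position=(30, 50), radius=2.0, mean_red=5000.0)]
        assert fq.estimate_background(img, masks, spot) == pytest.approx(100.0)

    def test_zero_image(self):
        masks = np.zeros((50, 50), dtype=int)
        masks[20:30, 20:30] = 1
        assert fq.estimate_background(np.zeros((50, 50)), masks) == 0.0

    def test_imax_is_brightest_spot_mean(self):
        spots = [
            fq.VesicleSpot(position=(0, 0), radius=2, mean_red=m)
            for m in (150.0, 210.0, 190.0)
        ]
        assert fq.estimate_imax(np.zeros((5, 5)), spots) == 210.0

    def test_imax_requires_spots(self):
        with pytest.raises(ValueError, match="manually"):
            fq.estimate_imax(np.zeros((5, 5)), [])


class TestSpotDetection:
    def test_blank_image_no_spots(self):
        assert fq.detect_vesicle_spots(np.full((64, 64), 100.0)) == []

    def test_planted_spots_all_found_at_their_positions(self, planted_scene):
        red = planted_scene.post_incubation[1]
        truth_pos = {
            (r, c) for r, c, _ in planted_scene.truth.spot_positions
        } | set(planted_scene.truth.reference_positions)
        spots = fq.detect_vesicle_spots(red)
        assert len(spots) == len(truth_pos)
        for s in spots:
            assert any(
                abs(s.position[0] - r) <= 1 and abs(s.position[1] - c) <= 1
                for r, c in truth_pos
            )

    def test_noiseless_reference_mean_equals_planted_amplitude(self, planted_scene):
        red = planted_scene.post_incubation[1]
        spots = fq.detect_vesicle_spots(red)
        assert fq.estimate_imax(red, spots) == pytest.approx(
            planted_scene.truth.I_max_red
        )

    def test_close_pair_merges_deterministically(self):
        img = np.full((64, 64), 100.0)
        for (r, c), amp in (((30, 30), 500.0), ((30, 31), 400.0)):
            rr, cc = np.mgrid[0:64, 0:64]
            img += amp * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * 1.2**2))
        first = fq.detect_vesicle_spots(img)
        second = fq.detect_vesicle_spots(img)
        assert len(first) == 1
        assert [s.position for s in first] == [s.position for s in second]


class TestClassification:
    def test_no_blue_signal_is_docked(self):
        blue = np.full((20, 20), 50.0)
        s = fq.VesicleSpot(position=(10, 10), radius=2.0, mean_red=500.0)
        assert fq.classify_spot(s, blue, I_back_blue=50.0, noise_sd=2.0) == "docked"
        assert s.single_frame_call

    def test_strong_blue_signal_is_hemifused(self):
        blue = np.full((20, 20), 50.0)
        blue[8:13, 8:13] += 40.0
        s = fq.VesicleSpot(position=(10, 10), radius=2.0, mean_red=500.0)
        assert fq.classify_spot(s, blue, I_back_blue=50.0, noise_sd=2.0) == "hemifused"

    def test_planted_classes_recovered(self, planted_scene):
        blue = planted_scene.post_incubation[0]
        labels = np.zeros(blue.shape, dtype=int)
        truth = {(r, c): k for r, c, k in planted_scene.truth.spot_positions}
        patch_level = float(np.median(blue[blue > 500]))
        for (r, c), kind in truth.items():
            s = fq.VesicleSpot(position=(r, c), radius=2.5, mean_red=0.0)
            assert fq.classify_spot(s, blue, patch_level, noise_sd=1.0) == kind


class TestExclusion:
    def test_uniform_patch_nothing_excluded(self):
        pix = np.full(400, 50.0)
        cap = fq.exclusion_threshold(pix)
        assert cap >= 50.0
        assert np.all(pix <= cap)

    def test_bright_spot_pixels_capped(self):
        pix = np.full(400, 50.0)
        pix[:9] = 250.0
        cap = fq.exclusion_threshold(pix)
        assert np.mean(pix[pix <= cap]) == pytest.approx(50.0)

    def test_too_few_pixels(self):
        with pytest.raises(ValueError):
            fq.exclusion_threshold(np.full(5, 1.0))

    def test_adding_docked_spot_never_raises_patch_mean(self, planted_scene):
        red = planted_scene.post_incubation[1].copy()
        labels = np.zeros(red.shape, dtype=int)
        gt = planted_scene.truth.patches[0]
        # reconstruct the patch mask from the membrane-dye channel
        labels[planted_scene.post_incubation[0] > 500] = 1
        spots = fq.detect_vesicle_spots(red)
        base = fq.measure_patch_intensity(red, labels, 1, spots, 100.0, 1100.0)
        rr, cc = np.nonzero(labels)
        centre = (int(rr.mean()), int(cc.mean()))
        red2 = red.copy()
        red2[centre[0] - 1 : centre[0] + 2, centre[1] - 1 : centre[1] + 2] = 1050.0
        spot = fq.VesicleSpot(position=centre, radius=2.5, mean_red=1050.0)
        with_spot = fq.measure_patch_intensity(
            red2, labels, 1, spots + [spot], 100.0, 1100.0
        )
        assert with_spot.I_patch <= base.I_patch + 1e-9


class TestEventsAndScans:
    def test_no_spots_all_zero(self):
        assert fq.count_events([], np.zeros((10, 10), dtype=int)) == {}

    def test_planted_counts_exact(self, planted_scene):
        frames = planted_scene.post_incubation
        labels = (frames[0] > 500).astype(int)
        spots = fq.detect_vesicle_spots(frames[1])
        patch_level = float(np.median(frames[0][labels > 0]))
        for s in spots:
            baseline = patch_level if labels[s.position] else 10.0
            fq.classify_spot(s, frames[0], baseline, noise_sd=1.0)
        counts = fq.count_events(spots, labels)
        gt = planted_scene.truth.patches[0]
        assert counts[1]["docked"] == gt.n_docked
        assert counts[1]["hemifused"] == gt.n_hemifused
        # references sit off-patch and are tallied separately
        assert counts[None]["docked"] == len(planted_scene.truth.reference_positions)

    def test_straddling_spot_assigned_by_centre_pixel(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[:, :10] = 1
        s = fq.VesicleSpot(position=(10, 9), radius=3.0, mean_red=1.0)
        s.spot_class = "docked"
        counts = fq.count_events([s], labels)
        assert counts[1]["docked"] == 1

    def test_area_scan_self_normalises(self):
        blue = np.full((40, 40), 10.0)
        red = np.full((40, 40), 5.0)
        masks = np.zeros((40, 40), dtype=int)
        masks[10:30, 10:30] = 1
        blue[masks > 0] = 200.0
        b, r = fq.area_scan(blue, red, (15, 5, 25, 35), masks)
        inside = b[10:20]
        assert np.allclose(inside, 1.0)
        assert np.allclose(r, 5.0 / 200.0)

    def test_area_scan_height_one_box_is_raw_row(self):
        blue = np.linspace(1, 40, 40)[None, :].repeat(10, axis=0)
        masks = np.ones((10, 40), dtype=int)
        b, _ = fq.area_scan(blue, blue, (4, 0, 4, 39), masks)
        assert np.allclose(b, blue[4] / blue.mean())

    def test_area_scan_box_bounds_checked(self):
        with pytest.raises(ValueError, match="box"):
            fq.area_scan(np.zeros((10, 10)), np.zeros((10, 10)), (0, 0, 10, 5),
                         np.ones((10, 10), dtype=int))


class TestGUVAdhesion:
    def test_uniform_disc_mean(self):
        stack = np.full((5, 40, 40), 10.0)
        mask = np.zeros((40, 40), dtype=bool)
        mask[15:25, 15:25] = True
        stack[0][mask] = 80.0
        m = fq.guv_adhesion_intensity(stack, mask, I_back=10.0, I_max=110.0)
        assert m.I_patch == pytest.approx(80.0)

    def test_noiseless_guv_recovers_true_efficiency(self):
        stack, truth = generate_guv_stack(10.0, 6.0, voxel_size=0.25, F_eff=16.5, seed=0)
        n_xy = stack.shape[2]
        axis = (np.arange(n_xy) - n_xy // 2) * 0.25
        yy, xx = np.meshgrid(axis, axis, indexing="ij")
        mask = np.sqrt(yy**2 + xx**2) <= truth["R_i"] - 0.25
        m = fq.guv_adhesion_intensity(
            stack[1], mask, I_back=truth["I_back"], I_max=truth["I_max"]
        )
        assert fq.fusion_efficiency(m) == pytest.approx(16.5, abs=1e-9)

    def test_missing_substrate_slice_is_an_error(self):
        stack = np.full((5, 40, 40), 10.0)
        mask = np.zeros((40, 40), dtype=bool)
        mask[15:25, 15:25] = True
        with pytest.raises(ValueError, match="substrate"):
            fq.guv_adhesion_intensity(stack, mask)

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            fq.guv_adhesion_intensity(np.zeros((5, 10, 10)), np.zeros((10, 10), bool))
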