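"""Phase masks, partition coefficients, boundary enrichment, and GUV ring
segmentation, validated against generator ground truth."""

import numpy as np
import pytest

from hdlmem import partition, spt, synthetic
from hdlmem.partition import TwoChannelImage
from hdlmem.spt import Localization


def _intensity_image(kp_true, seed, density2=2e4, shape=(256, 256)):
    img = synthetic.gen_two_phase_image(
        density1=kp_true * density2, density2=density2, mode="pixel-intensity",
        shape=shape, pixel_size=100.0, seed=seed,
    )
    mask = partition.make_phase_mask(img.channel_marker)
    corrected = partition.background_correct(img.channel_signal, offset=100.0, clip=False)
    return TwoChannelImage(img.channel_marker, corrected, 100.0), mask, img


class TestBackgroundCorrect:
    def test_offset_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(50.0, (64, 64)).astype(float)
        a = partition.background_correct(base)
        b = partition.background_correct(base + 37.0)
        assert np.allclose(a, b)

    def test_pure_noise_residual_near_zero(self):
        rng = np.random.default_rng(1)
        img = rng.normal(100.0, 3.0, (128, 128))
        out = partition.background_correct(img, clip=False)
        assert abs(out.mean()) < 1.0

    def test_uniform_image_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="uniform"):
            out = partition.background_correct(np.full((16, 16), 9.0))
        assert np.all(out == 0.0)

    def test_saturation_warns(self):
        img = np.full((8, 8), 10.0)
        img[0, 0] = 65535.0
        with pytest.warns(UserWarning, match="saturated"):
            partition.background_correct(img, offset=0.0, saturation=65535.0)


class TestPhaseMask:
    def test_jaccard_against_truth(self):
        img = synthetic.gen_two_phase_image(shape=(256, 256), seed=0)
        mask = partition.make_phase_mask(img.channel_marker)
        truth = img.truth.extras["labels"]
        inter = np.sum((mask.labels == 1) & (truth == 1))
        union = np.sum((mask.labels == 1) | (truth == 1))
        assert inter / union >= 0.99

    def test_invert_swaps_labels(self):
        img = synthetic.gen_two_phase_image(shape=(128, 128), seed=1)
        mask = partition.make_phase_mask(img.channel_marker)
        inv = partition.make_phase_mask(img.channel_marker, invert=True)
        assert np.array_equal(inv.labels, 3 - mask.labels)

    def test_unimodal_marker_degenerate(self):
        rng = np.random.default_rng(2)
        with pytest.warns(UserWarning, match="degenerate"):
            mask = partition.make_phase_mask(rng.normal(100, 1.0, (64, 64)), min_area=0)
        assert mask.degenerate


class TestKpIntensity:
    def test_uniform_density_gives_unity(self):
        image, mask, _ = _intensity_image(1.0, seed=3)
        res = partition.compute_kp_intensity(image, mask)
        assert res.kp == pytest.approx(1.0, abs=3 * max(res.se_kp, 0.01))

    @pytest.mark.parametrize("kp_true", [0.068, 0.006])
    def test_gel_phase_ratios_recovered(self, kp_true):
        image, mask, _ = _intensity_image(kp_true, seed=4)
        res = partition.compute_kp_intensity(image, mask)
        assert res.kp == pytest.approx(kp_true, rel=0.15)

    def test_scale_invariance(self):
        image, mask, _ = _intensity_image(0.5, seed=5)
        res = partition.compute_kp_intensity(image, mask)
        doubled = TwoChannelImage(image.channel_marker, image.channel_signal * 2, 100.0)
        res2 = partition.compute_kp_intensity(doubled, mask)
        assert res2.kp == pytest.approx(res.kp, rel=1e-9)

    def test_label_swap_inverts_kp(self):
        image, mask, _ = _intensity_image(0.25, seed=6)
        res = partition.compute_kp_intensity(image, mask)
        res_sw = partition.compute_kp_intensity(image, mask.swapped())
        assert res_sw.kp == pytest.approx(1.0 / res.kp, rel=1e-9)

    def test_empty_phase_reports_lower_bound(self):
        image, mask, _ = _intensity_image(0.5, seed=7)
        zeroed = TwoChannelImage(
            image.channel_marker,
            np.where(mask.labels == 2, 0.0, image.channel_signal),
            100.0,
        )
        res = partition.compute_kp_intensity(zeroed, mask)
        assert "lower_bound" in res.flags and np.isinf(res.kp)

    def test_bootstrap_se_shrinks_with_tiles(self):
        image, mask, _ = _intensity_image(1.0, seed=8)
        se4 = partition.compute_kp_intensity(image, mask, n_tiles=4).se_kp
        se8 = partition.compute_kp_intensity(image, mask, n_tiles=8).se_kp
        # ~1/sqrt(tiles): quadrupling tile count should not grow the SE
        assert se8 <= se4 * 1.5


class TestKpSpots:
    def test_uniform_spots_give_unity(self):
        img = synthetic.gen_two_phase_image(
            density1=0.3, density2=0.3, mode="point-emitters", shape=(256, 256), seed=9
        )
        mask = partition.make_phase_mask(img.channel_marker)
        locs = [Localization(e[0], e[1], 0) for e in img.truth.extras["emitters"]]
        res = partition.compute_kp_spots(locs, mask, pixel_size=100.0)
        assert res.kp == pytest.approx(1.0, abs=3 * res.se_kp)

    def test_detected_spot_ratio_recovers_truth(self):
        img = synthetic.gen_two_phase_image(
            density1=0.3, density2=0.1, mode="point-emitters", shape=(384, 384), seed=10
        )
        mask = partition.make_phase_mask(img.channel_marker)
        locs = spt.detect_spots(img.channel_signal, pixel_size=100.0)
        res = partition.compute_kp_spots(locs, mask, pixel_size=100.0)
        assert res.kp == pytest.approx(3.0, rel=0.2)

    def test_intensity_and_spot_mode_agree(self):
        img = synthetic.gen_two_phase_image(
            density1=0.3, density2=0.1, mode="point-emitters", shape=(384, 384), seed=11
        )
        mask = partition.make_phase_mask(img.channel_marker)
        locs = spt.detect_spots(img.channel_signal, pixel_size=100.0)
        spots = partition.compute_kp_spots(locs, mask, pixel_size=100.0)
        corrected = partition.background_correct(img.channel_signal, offset=100.0, clip=False)
        inten = partition.compute_kp_intensity(
            TwoChannelImage(img.channel_marker, corrected, 100.0), mask
        )
        assert inten.kp == pytest.approx(spots.kp, rel=3 * (spots.se_kp / spots.kp) + 0.1)

    def test_all_spots_in_one_phase_lower_bound(self):
        img = synthetic.gen_two_phase_image(shape=(128, 128), seed=12)
        mask = partition.make_phase_mask(img.channel_marker)
        cols = np.argwhere(mask.labels == 1)
        locs = [
            Localization((c[1] + 0.5) * 0.1, (c[0] + 0.5) * 0.1, 0) for c in cols[:50]
        ]
        res = partition.compute_kp_spots(locs, mask, pixel_size=100.0)
        assert "lower_bound" in res.flags


class TestBoundaryFraction:
    def test_uniform_spots_match_band_area_null(self):
        img = synthetic.gen_two_phase_image(
            density1=0.3, density2=0.3, mode="point-emitters", shape=(256, 256), seed=13
        )
        mask = partition.make_phase_mask(img.channel_marker)
        locs = [Localization(e[0], e[1], 0) for e in img.truth.extras["emitters"]]
        out = partition.boundary_fraction(locs, mask, dist=200.0, pixel_size=100.0)
        n = out["n"]
        se = np.sqrt(out["null_fraction"] * (1 - out["null_fraction"]) / n)
        assert out["fraction"] == pytest.approx(out["null_fraction"], abs=4 * se)

    def test_all_spots_on_boundary(self):
        img = synthetic.gen_two_phase_image(shape=(128, 128), seed=14)
        mask = partition.make_phase_mask(img.channel_marker)
        rows = np.argwhere(mask.boundary)
        locs = [Localization((r[1] + 0.5) * 0.1, (r[0] + 0.5) * 0.1, 0) for r in rows]
        out = partition.boundary_fraction(locs, mask, dist=100.0, pixel_size=100.0)
        assert out["fraction"] == 1.0

    def test_enriched_fraction_recovered(self):
        """30% of spots seeded into the boundary band, the rest uniform:
        the measured enrichment matches construction within +-0.05."""
        rng = np.random.default_rng(15)
        img = synthetic.gen_two_phase_image(shape=(256, 256), seed=15)
        mask = partition.make_phase_mask(img.channel_marker)
        from scipy import ndimage

        band = ndimage.distance_transform_edt(~mask.boundary) * 100.0 <= 200.0
        band_px = np.argwhere(band)
        n = 1000
        n_b = 300
        picks = band_px[rng.integers(0, len(band_px), n_b)]
        locs = [Localization((c + 0.5) * 0.1, (r + 0.5) * 0.1, 0) for r, c in picks]
        locs += [
            Localization(x, y, 0)
            for x, y in rng.uniform(0, 25.6, (n - n_b, 2))
        ]
        out = partition.boundary_fraction(locs, mask, dist=200.0, pixel_size=100.0)
        expected = 0.3 + 0.7 * out["null_fraction"]
        assert out["fraction"] == pytest.approx(expected, abs=0.05)

    def test_empty_boundary_rejected(self):
        mask = partition.PhaseMask(
            labels=np.ones((8, 8), dtype=np.uint8),
            boundary=np.zeros((8, 8), dtype=bool),
        )
        with pytest.raises(ValueError, match="boundary"):
            partition.boundary_fraction([Localization(0.1, 0.1, 0)], mask, dist=200.0)


class TestGuvSegmentation:
    def test_radius_recovered_within_2_percent(self):
        guv = synthetic.gen_guv_image(radius=10.0, interior_density=0.0, seed=16)
        seg = partition.segment_guv(guv.stack, pixel_size=200.0)
        assert seg.radius_um == pytest.approx(10.0, rel=0.02)

    def test_ring_mask_jaccard_against_truth(self):
        guv = synthetic.gen_guv_image(radius=10.0, interior_density=0.0, seed=17)
        seg = partition.segment_guv(guv.stack, pixel_size=200.0)
        truth_ring = guv.truth.extras["ring_mask"]
        inter = np.logical_and(seg.ring_mask, truth_ring).sum()
        union = np.logical_or(seg.ring_mask, truth_ring).sum()
        assert inter / union >= 0.8

    def test_equatorial_slice_near_truth(self):
        """Adjacent slices differ by <1% in ring circumference, so shot noise
        legitimately blurs the argmax by a slice or two."""
        guv = synthetic.gen_guv_image(radius=10.0, seed=18)
        seg = partition.segment_guv(guv.stack, pixel_size=200.0)
        assert abs(seg.slice_index - guv.truth.parameters["equatorial_index"]) <= 2

    def test_zero_interior_measures_zero_density(self):
        noise = synthetic.CameraNoise(offset=0.0, read_sd=0.0)
        guv = synthetic.gen_guv_image(radius=8.0, interior_density=0.0, noise=noise, seed=19)
        seg = partition.segment_guv(guv.stack, pixel_size=200.0)
        assert seg.interior_density["membrane"] == pytest.approx(0.0, abs=0.5)

    def test_density_definition_matches_pixel_loop_oracle(self):
        guv = synthetic.gen_guv_image(radius=8.0, seed=20)
        seg = partition.segment_guv(guv.stack, pixel_size=200.0)
        img = guv.stack[seg.slice_index]
        total, count = 0.0, 0
        for r, c in np.argwhere(seg.ring_mask):
            total += img[r, c]
            count += 1
        assert seg.density["membrane"] == pytest.approx(total / count, rel=1e-12)

    def test_flat_stack_errors(self):
        with pytest.raises(ValueError, match="no ring"):
            partition.segment_guv(np.zeros((5, 64, 64)), pixel_size=200.0)
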