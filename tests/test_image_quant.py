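"""Thresholding, segmentation, ratio imaging, band spacing, densitometry."""
import numpy as np
import pandas as pd
import pytest

from cardiomech.datatypes import Patch
from cardiomech.image_quant import (
    band_spacing,
    classify_mito_networks,
    densitometry_normalize,
    despeckle,
    huang_threshold,
    jc1_ratio,
    li_threshold,
    nuclear_mean_intensity,
    segment_patches,
    to_8bit,
    weighted_mean_intensity,
)
from cardiomech.synth import (
    ImageSpec,
    ObjectSpec,
    generate_ratio_pair,
    generate_striation_image,
)


def _patch(area, mean, pid=1):
    return Patch(id=pid, pixels=np.zeros((1, 2), dtype=int), area=area, mean_intensity=mean)


class TestThresholds:
    @pytest.mark.parametrize("method", [li_threshold, huang_threshold])
    def test_two_valued_image_threshold_separates_modes(self, method, rng):
        img = np.where(rng.random((100, 100)) < 0.1, 200.0, 10.0)
        t = method(img)
        assert 10.0 < t < 200.0

    @pytest.mark.parametrize("method", [li_threshold, huang_threshold])
    def test_constant_image_rejected(self, method):
        with pytest.raises(ValueError):
            method(np.full((10, 10), 42.0))

    @pytest.mark.parametrize("method", [li_threshold, huang_threshold])
    def test_bimodal_truth_recovery_above_99_percent(self, method, bimodal_image):
        img, truth = bimodal_image
        agreement = ((img > method(img)) == truth).mean()
        assert agreement >= 0.99

    @pytest.mark.parametrize("method", [li_threshold, huang_threshold])
    def test_positive_scale_equivariance(self, method, bimodal_image):
        img, _ = bimodal_image
        t1, t3 = method(img), method(3.0 * img)
        assert t3 == pytest.approx(3.0 * t1, rel=0.02)

    @pytest.mark.parametrize("method", [li_threshold, huang_threshold])
    def test_shift_invariance_of_binarisation(self, method, bimodal_image):
        img, _ = bimodal_image
        m1 = img > method(img)
        m2 = (img + 500.0) > method(img + 500.0)
        assert (m1 == m2).mean() >= 0.99

    def test_li_matches_independent_fixed_point_iteration(self, bimodal_image):
        # oracle: the minimum-cross-entropy threshold satisfies the
        # fixed point t = (mu_below - mu_above) / (ln mu_below - ln mu_above)
        img, _ = bimodal_image
        t = img.mean()
        for _ in range(200):
            mu_fg = img[img > t].mean()
            mu_bg = img[img <= t].mean()
            t_new = (mu_bg - mu_fg) / (np.log(mu_bg) - np.log(mu_fg))
            if abs(t_new - t) < 1e-9:
                break
            t = t_new
        assert li_threshold(img) == pytest.approx(t, rel=1e-3)

    def test_li_and_huang_masks_agree_on_separated_modes(self, bimodal_image):
        img, _ = bimodal_image
        agree = ((img > li_threshold(img)) == (img > huang_threshold(img))).mean()
        assert agree >= 0.98


class TestPreprocessing:
    def test_despeckle_removes_isolated_outlier(self):
        img = np.full((9, 9), 10.0)
        img[4, 4] = 1000.0
        assert despeckle(img)[4, 4] == 10.0

    def test_to_8bit_spans_full_range(self, rng):
        img = rng.random((20, 20)) * 7 + 3
        out = to_8bit(img)
        assert out.dtype == np.uint8
        assert out.min() == 0 and out.max() == 255

    def test_to_8bit_constant_image_rejected(self):
        with pytest.raises(ValueError):
            to_8bit(np.ones((5, 5)))


class TestSegmentPatches:
    def test_empty_mask_gives_no_patches(self):
        assert segment_patches(np.zeros((10, 10)), np.zeros((10, 10), bool)) == []

    def test_two_disjoint_squares(self):
        mask = np.zeros((20, 20), bool)
        mask[2:7, 2:7] = True
        mask[12:17, 12:17] = True
        img = np.ones((20, 20))
        patches = segment_patches(img, mask, pixel_size=2.0)
        assert len(patches) == 2
        assert sorted(p.area for p in patches) == [100.0, 100.0]  # 25 px * 4 um^2

    def test_diagonal_touch_is_one_patch_under_8_connectivity(self):
        mask = np.zeros((6, 6), bool)
        mask[1, 1] = mask[2, 2] = True
        patches = segment_patches(np.ones((6, 6)), mask)
        assert len(patches) == 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            segment_patches(np.zeros((5, 5)), np.zeros((6, 6), bool))


class TestWeightedMean:
    def test_single_patch_returns_its_mean(self):
        assert weighted_mean_intensity([_patch(10.0, 7.5)]) == 7.5

    def test_hand_computed_weighting(self):
        assert weighted_mean_intensity([_patch(1.0, 4.0), _patch(3.0, 8.0, 2)]) == 7.0

    def test_equals_pixel_population_mean(self, rng):
        # brute-force oracle: mean over the union mask of all patch pixels
        img = rng.random((64, 64)) * 100
        mask = rng.random((64, 64)) < 0.2
        patches = segment_patches(img, mask, pixel_size=0.65)
        if not patches:
            pytest.skip("degenerate draw")
        assert weighted_mean_intensity(patches) == pytest.approx(
            img[mask].mean(), rel=1e-12
        )

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            weighted_mean_intensity([])


class TestMitoClassification:
    def test_boundary_area_is_small(self):
        (rec,) = classify_mito_networks([_patch(100.0, 1.0)])
        assert rec.size_class == "small"

    def test_just_above_boundary_is_large(self):
        (rec,) = classify_mito_networks([_patch(100.1, 1.0)])
        assert rec.size_class == "large"

    def test_empty_input_empty_output(self):
        assert classify_mito_networks([]) == []

    def test_partition_is_exhaustive_and_exclusive(self, rng):
        patches = [_patch(float(a), 1.0, i) for i, a in enumerate(rng.uniform(0, 300, 100))]
        records = classify_mito_networks(patches)
        assert len(records) == 100
        small = sum(r.size_class == "small" for r in records)
        large = sum(r.size_class == "large" for r in records)
        assert small + large == 100


class TestJc1Ratio:
    def test_identical_channels_give_unit_ratio(self, rng):
        img = rng.random((50, 50)) * 100 + 50
        assert jc1_ratio(img, img, floor=0.0).mean_ratio == pytest.approx(1.0)

    def test_synthetic_pair_recovers_generating_ratio(self):
        spec = ImageSpec(shape=(96, 96), objects=[ObjectSpec(("disk", (48, 48), 20), 200.0)], background=5.0)
        pair = generate_ratio_pair(spec, 2.5)
        result = jc1_ratio(pair.aggregate, pair.monomer)
        assert result.mean_ratio == pytest.approx(2.5, rel=1e-9)

    def test_all_below_floor_gives_undefined_mean(self):
        mono = np.full((10, 10), 1.0)
        result = jc1_ratio(mono * 2, mono, floor=5.0)
        assert np.isnan(result.mean_ratio)
        assert not result.valid_mask.any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            jc1_ratio(np.zeros((5, 5)), np.zeros((6, 6)), floor=0.0)

    def test_error_decays_with_noise(self):
        spec_base = dict(
            shape=(128, 128),
            objects=[ObjectSpec(("disk", (64, 64), 50), 200.0)],
            background=5.0,
            seed=9,
        )
        errors = []
        for noise in (16.0, 8.0, 4.0):
            pair = generate_ratio_pair(ImageSpec(noise_sd=noise, **spec_base), 2.5)
            result = jc1_ratio(pair.aggregate, pair.monomer, floor=100.0)
            errors.append(abs(result.mean_ratio - 2.5))
        assert errors[0] > errors[1] > errors[2]


class TestNuclearMean:
    def test_uniform_signal_returns_that_value(self):
        mask = np.zeros((10, 10), bool)
        mask[2:5, 2:5] = True
        per, avg = nuclear_mean_intensity(mask, np.full((10, 10), 42.0))
        assert per.tolist() == [42.0]
        assert avg == 42.0

    def test_instance_averaging_not_pixel_averaging(self):
        mask = np.zeros((20, 20), bool)
        mask[1:3, 1:3] = True  # 4 px at 5
        mask[10:16, 10:16] = True  # 36 px at 15
        img = np.zeros((20, 20))
        img[1:3, 1:3] = 5.0
        img[10:16, 10:16] = 15.0
        per, avg = nuclear_mean_intensity(mask, img)
        assert sorted(per.tolist()) == [5.0, 15.0]
        assert avg == 10.0  # not the pooled pixel mean (14.0)

    def test_no_nuclei_rejected(self):
        with pytest.raises(ValueError):
            nuclear_mean_intensity(np.zeros((5, 5), bool), np.zeros((5, 5)))


class TestBandSpacing:
    def test_known_period_recovered(self):
        img = generate_striation_image(1.65, 0.1, shape=(200, 200), orientation=0)
        mean, _ = band_spacing(img, 0.1)
        assert mean == pytest.approx(1.65, abs=0.1)  # one pixel equivalent

    def test_rotation_by_90_degrees_leaves_spacing_unchanged(self):
        img = generate_striation_image(1.65, 0.1, shape=(200, 200), orientation=0)
        m1, _ = band_spacing(img, 0.1)
        m2, _ = band_spacing(np.rot90(img), 0.1)
        assert m2 == pytest.approx(m1, rel=1e-6)

    def test_pixel_size_scales_reported_spacing(self):
        img = generate_striation_image(1.65, 0.1, shape=(200, 200), orientation=0)
        m1, _ = band_spacing(img, 0.1)
        m2, _ = band_spacing(img, 0.2)
        assert m2 == pytest.approx(2.0 * m1)

    def test_too_few_bands_rejected(self):
        img = np.zeros((50, 50))
        img[25, :] = 1.0
        with pytest.raises(ValueError):
            band_spacing(img, 0.1)


class TestDensitometry:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["sample", "protein", "band_intensity", "lane_total_protein"]
        )

    def test_identical_lanes_normalise_to_one(self):
        table = self._table([("CPC", "cTnT", 5.0, 2.0)] * 3 + [("iCM", "cTnT", 5.0, 2.0)])
        out = densitometry_normalize(table, "CPC")
        assert np.allclose(out["normalized"], 1.0)

    def test_hand_computed_normalisation(self):
        table = self._table([("ref", "p", 2.0, 1.0), ("other", "p", 4.0, 1.0)])
        out = densitometry_normalize(table, "ref")
        assert out["normalized"].tolist() == [1.0, 2.0]

    def test_reference_group_mean_is_exactly_one(self, rng):
        rows = [("CPC", "p", float(rng.uniform(1, 5)), float(rng.uniform(1, 3))) for _ in range(4)]
        rows += [("mCM", "p", 3.0, 1.5)]
        out = densitometry_normalize(self._table(rows), "CPC")
        ref_mean = out.loc[out["sample"] == "CPC", "normalized"].mean()
        assert ref_mean == pytest.approx(1.0, rel=1e-12)

    def test_fallback_reference_used_when_primary_undetectable(self):
        # beta-actin-like case: reference group signal absent, fall back
        table = self._table(
            [("CPC", "bactin", 0.0, 1.0), ("mCM", "bactin", 4.0, 2.0), ("iCM", "bactin", 2.0, 2.0)]
        )
        out = densitometry_normalize(table, "CPC", fallback_group="mCM")
        assert set(out["reference_used"]) == {"mCM"}
        assert out.loc[out["sample"] == "mCM", "normalized"].mean() == pytest.approx(1.0)

    def test_zero_lane_total_rejected(self):
        with pytest.raises(ValueError):
            densitometry_normalize(self._table([("CPC", "p", 1.0, 0.0)]), "CPC")
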