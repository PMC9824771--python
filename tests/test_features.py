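"""Feature extraction: quadrant split, skin band, histogram moments, Otsu
density, right/left ratios, and the bundled reference cohort."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ibccad.features import (
    FeatureVector,
    band_moments,
    compute_features,
    density_mean,
    extract_skin_band,
    intensity_pmf,
    load_reference_cohort,
    otsu_threshold,
    segment_lower_quadrant,
)
from ibccad.image import BilateralStudy, MammogramImage
from ibccad.phantom import (
    PhantomParams,
    SidePhantomParams,
    generate_bilateral_phantom,
    _arc_distance,
)
from ibccad.preprocess import (
    NippleLocation,
    locate_nipple,
    remove_artifacts,
    segment_breast,
)


def brute_force_otsu(values):
    """Exhaustive 256-level search for the between-class variance maximizer."""
    z = np.round(np.asarray(values, float).ravel() * 255).astype(int)
    best_t, best_v = None, -1.0
    for t in range(255):
        lo, hi = z[z <= t], z[z > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo) / len(z), len(hi) / len(z)
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


@pytest.fixture(scope="module")
def segmented(symmetric_study):
    _, study, _ = symmetric_study
    bm = segment_breast(remove_artifacts(study.right))
    return bm, locate_nipple(bm, "CC")


class TestLowerQuadrant:
    def test_apex_nipple_halves_the_breast(self, segmented):
        bm, nip = segmented
        roi = segment_lower_quadrant(bm, nip)
        assert roi.mask.sum() / bm.mask.sum() == pytest.approx(0.5, abs=0.02)

    def test_roi_is_subset_of_mask_on_inferior_side(self, segmented):
        bm, nip = segmented
        roi = segment_lower_quadrant(bm, nip)
        assert not (roi.mask & ~bm.mask).any()
        rows = np.nonzero(roi.mask)[0]
        assert rows.min() >= nip.point[0]

    def test_line_outside_mask_raises(self, segmented):
        bm, _ = segmented
        outside = NippleLocation(point=(5, 5), direction=(0.0, 1.0))
        with pytest.raises(ValueError, match="nipple line"):
            segment_lower_quadrant(bm, outside)

    def test_mirrored_input_gives_mirrored_roi(self, symmetric_study):
        _, study, _ = symmetric_study
        clean = remove_artifacts(study.right)
        bm = segment_breast(clean)
        roi = segment_lower_quadrant(bm, locate_nipple(bm, "CC"))
        flipped = MammogramImage(np.fliplr(clean.pixels))
        bm_f = segment_breast(flipped)
        roi_f = segment_lower_quadrant(bm_f, locate_nipple(bm_f, "CC"))
        np.testing.assert_array_equal(roi_f.mask, np.fliplr(roi.mask))


class TestSkinBand:
    def test_band_overlaps_constructed_band(self, symmetric_study):
        params, _, _ = symmetric_study
        thin = replace(
            params,
            right=replace(params.right, skin_band_thickness_px=3),
            left=replace(params.left, skin_band_thickness_px=3),
        )
        study, _ = generate_bilateral_phantom(thin)
        h, w = study.right.shape
        rows, cols = np.mgrid[0:h, 0:w]
        a, b = thin.right.half_axes_px
        ellipse = (cols / b) ** 2 + ((rows - h / 2) / a) ** 2 <= 1
        nipple = (rows - h / 2) ** 2 + (cols - b) ** 2 <= 9
        mask = ellipse | nipple
        constructed = mask & (_arc_distance(mask) <= 3)

        bm = segment_breast(remove_artifacts(study.right))
        roi = segment_lower_quadrant(bm, locate_nipple(bm, "CC"))
        band = extract_skin_band(bm, roi, 3)
        constructed_lower = constructed & roi.mask
        iou = (band.mask & constructed_lower).sum() / (
            band.mask | constructed_lower
        ).sum()
        assert iou >= 0.90

    def test_band_saturates_to_roi_for_huge_width(self, segmented):
        bm, nip = segmented
        roi = segment_lower_quadrant(bm, nip)
        band = extract_skin_band(bm, roi, 10_000)
        np.testing.assert_array_equal(band.mask, roi.mask)

    def test_band_pixels_within_width_of_arc(self, segmented):
        from scipy import ndimage

        bm, nip = segmented
        roi = segment_lower_quadrant(bm, nip)
        band = extract_skin_band(bm, roi, 4)
        arc_mask = np.zeros_like(bm.mask)
        arc_mask[bm.arc[:, 0], bm.arc[:, 1]] = True
        dist = ndimage.distance_transform_edt(~arc_mask)
        assert dist[band.mask].max() <= 4

    def test_invalid_width_rejected(self, segmented):
        bm, nip = segmented
        roi = segment_lower_quadrant(bm, nip)
        with pytest.raises(ValueError):
            extract_skin_band(bm, roi, 0)


class TestPMFAndMoments:
    def test_two_point_region(self):
        pmf = intensity_pmf(np.array([0.0, 1.0, 0.0, 1.0]))
        assert pmf.probs[0] == pytest.approx(0.5)
        assert pmf.probs[255] == pytest.approx(0.5)

    def test_uniform_region_concentrates_at_one_level(self):
        pmf = intensity_pmf(np.full(100, 0.5))
        assert pmf.probs[128] == 1.0

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                 min_size=1, max_size=200)
    )
    def test_pmf_normalized_and_nonnegative(self, values):
        pmf = intensity_pmf(np.array(values))
        assert abs(pmf.probs.sum() - 1.0) < 1e-9
        assert (pmf.probs >= 0).all()

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            intensity_pmf(np.array([]))

    def test_three_point_mean(self):
        mu, _ = band_moments(intensity_pmf(np.array([0.0, 0.5, 1.0])))
        # levels 0, 128, 255: mean is pulled by round(0.5*255)=128
        assert mu == pytest.approx((0 + 128 + 255) / 3 / 255)

    def test_constant_region_has_zero_sd(self):
        _, sigma = band_moments(intensity_pmf(np.full(10, 0.3)))
        assert sigma == 0.0

    def test_moments_equal_direct_sample_statistics(self, rng):
        """Histogram moments must equal plain sample mean/population SD."""
        values = rng.random(1000)
        z = np.round(values * 255)
        mu, sigma = band_moments(intensity_pmf(values))
        assert mu == pytest.approx(z.mean() / 255, abs=1e-12)
        assert sigma == pytest.approx(z.std() / 255, abs=1e-12)


class TestOtsu:
    def test_balanced_bimodal_threshold_between_modes(self):
        values = np.r_[np.full(50, 0.2), np.full(50, 0.8)]
        t = otsu_threshold(values)
        # every split between the modes maximizes the between-class
        # variance; the tie breaks to the lowest maximizer (the low mode)
        assert 51 <= t < 204
        assert t == brute_force_otsu(values)

    def test_two_pixel_region(self):
        values = np.array([0.0, 1.0])
        assert otsu_threshold(values) == brute_force_otsu(values)

    def test_constant_region_raises(self):
        with pytest.raises(ValueError, match="constant"):
            otsu_threshold(np.full(10, 0.7))

    def test_matches_exhaustive_oracle_on_random_histograms(self, rng):
        for _ in range(25):
            n_modes = rng.integers(2, 5)
            centers = rng.random(n_modes)
            values = np.clip(
                np.concatenate(
                    [c + 0.05 * rng.standard_normal(rng.integers(5, 60))
                     for c in centers]
                ),
                0,
                1,
            )
            assert otsu_threshold(values) == brute_force_otsu(values)


class TestDensity:
    def test_half_above_threshold(self):
        values = np.r_[np.full(10, 0.2), np.full(10, 0.9)]
        assert density_mean(values, 128) == pytest.approx(0.5)

    def test_all_below_threshold(self):
        assert density_mean(np.full(10, 0.1), 128) == 0.0

    def test_phantom_density_recovered_from_construction(self):
        params = PhantomParams(
            noise_sd=0.0,
            seed=9,
            right=SidePhantomParams(interior_density_fraction=0.30),
            left=SidePhantomParams(interior_density_fraction=0.30),
        )
        study, _ = generate_bilateral_phantom(params)
        fv = compute_features(study)
        assert fv.side_stats["right"].gamma == pytest.approx(0.30, abs=0.02)
        assert fv.side_stats["left"].gamma == pytest.approx(0.30, abs=0.02)


class TestComputeFeatures:
    def test_symmetric_phantom_gives_unit_ratios(self, symmetric_study):
        _, study, _ = symmetric_study
        fv = compute_features(study)
        for v in fv.values():
            assert v == pytest.approx(1.0, abs=0.02)

    def test_side_swap_inverts_every_ratio(self, asymmetric_study):
        _, study, _ = asymmetric_study
        fv = compute_features(study)
        fv_swapped = compute_features(study.swapped())
        for v, vs in zip(fv.values(), fv_swapped.values()):
            assert vs == pytest.approx(1.0 / v, rel=1e-9)

    def test_left_ibc_pattern_halves_the_mean_ratio(self, asymmetric_study):
        """Left band intensity twice the right's gives f1 near 0.5."""
        _, study, _ = asymmetric_study
        fv = compute_features(study.swapped())  # left brighter
        assert fv.f1 == pytest.approx(0.5, rel=0.10)

    def test_intensity_scaling_preserves_ratio_semantics(self, symmetric_study):
        _, study, _ = symmetric_study
        fv = compute_features(study)
        scaled = BilateralStudy(
            right=MammogramImage(study.right.pixels * 0.6),
            left=MammogramImage(study.left.pixels * 0.6),
            view=study.view,
        )
        fv_scaled = compute_features(scaled)
        assert fv_scaled.f3 == fv.f3
        assert abs(fv_scaled.f1 - fv.f1) / fv.f1 < 0.05

    def test_feature_vector_rejects_nonpositive_values(self):
        with pytest.raises(ValueError):
            FeatureVector(f1=0.0, f2=1.0, f3=1.0)
        with pytest.raises(ValueError):
            FeatureVector(f1=1.0, f2=np.inf, f3=1.0)


class TestReferenceCohort:
    def test_cohort_composition(self, cohort):
        assert len(cohort) == 14
        assert sum(c.label == "IBC" for c in cohort) == 6

    def test_first_ibc_case_values(self, cohort):
        case = next(c for c in cohort if c.case_id == "IBC_1")
        assert case.values() == (0.55, 0.48, 0.48)
        assert case.label == "IBC"
        assert case.affected_side == "left"

    def test_third_non_ibc_case_values(self, cohort):
        case = next(c for c in cohort if c.case_id == "NON-IBC_3")
        assert case.values() == (1.01, 1.46, 0.73)
        assert case.label == "non-IBC"
        assert case.affected_side is None
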