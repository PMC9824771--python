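"""Preprocessing: artifact removal, segmentation, orientation, nipple,
contrast and decorrelation stretches, and mirror-symmetry invariants."""

from dataclasses import replace

import numpy as np
import pytest

from ibccad.features import extract_skin_band, segment_lower_quadrant
from ibccad.image import MammogramImage
from ibccad.phantom import generate_bilateral_phantom
from ibccad.preprocess import (
    AmbiguousOrientationError,
    BlankImageError,
    contrast_stretch,
    decorrelation_stretch,
    detect_orientation,
    locate_nipple,
    remove_artifacts,
    segment_breast,
)


def _segmented(study):
    return segment_breast(remove_artifacts(study.right))


class TestRemoveArtifacts:
    def test_recovers_artifact_free_phantom(self, symmetric_study):
        params, study, _ = symmetric_study
        with_artifacts, _ = generate_bilateral_phantom(
            replace(params, annotation_artifacts=True)
        )
        cleaned = remove_artifacts(with_artifacts.right)
        np.testing.assert_allclose(cleaned.pixels, study.right.pixels, atol=1e-12)

    def test_idempotent_on_clean_image(self, symmetric_study):
        _, study, _ = symmetric_study
        once = remove_artifacts(study.right)
        twice = remove_artifacts(once)
        np.testing.assert_array_equal(once.pixels, twice.pixels)

    def test_blank_image_raises(self):
        with pytest.raises(BlankImageError):
            remove_artifacts(MammogramImage(np.zeros((64, 64))))


class TestSegmentBreast:
    def test_mask_area_matches_analytic_half_ellipse(self, symmetric_study):
        params, study, _ = symmetric_study
        bm = _segmented(study)
        a, b = params.right.half_axes_px
        analytic = np.pi * a * b / 2.0
        assert bm.mask.sum() == pytest.approx(analytic, rel=0.02)

    def test_chest_side_matches_construction(self, symmetric_study):
        _, study, _ = symmetric_study
        assert _segmented(study).chest_side == "left"
        bm_left = segment_breast(remove_artifacts(study.left))
        assert bm_left.chest_side == "right"

    def test_inverted_polarity_image_gives_same_mask(self, symmetric_study):
        _, study, _ = symmetric_study
        bm = _segmented(study)
        inverted = MammogramImage(1.0 - study.right.pixels)
        bm_inv = segment_breast(inverted)
        assert (bm.mask ^ bm_inv.mask).mean() < 0.01

    def test_foreground_touching_three_edges_is_ambiguous(self):
        px = np.zeros((128, 128))
        px[:, :50] = 0.8  # slab touching top, bottom and left edges
        with pytest.raises(AmbiguousOrientationError):
            segment_breast(MammogramImage(px))

    def test_mask_is_single_connected_component(self, symmetric_study):
        from scipy import ndimage

        _, study, _ = symmetric_study
        _, n = ndimage.label(_segmented(study).mask)
        assert n == 1


class TestOrientation:
    def test_cc_phantom_detected_as_cc(self, symmetric_study):
        _, study, _ = symmetric_study
        view, confidence = detect_orientation(_segmented(study))
        assert view == "CC"
        assert confidence < 0.6

    def test_mlo_phantom_detected_as_mlo(self, symmetric_study):
        params, _, _ = symmetric_study
        study, _ = generate_bilateral_phantom(replace(params, view="MLO"))
        for img in (study.right, study.left):
            view, confidence = detect_orientation(
                segment_breast(remove_artifacts(img))
            )
            assert view == "MLO"
            assert confidence >= 0.6

    def test_corner_occupancy_at_cutoff_ties_to_mlo(self, symmetric_study):
        _, study, _ = symmetric_study
        bm = _segmented(study)
        _, confidence = detect_orientation(bm)
        view, _ = detect_orientation(bm, cutoff=confidence)
        assert view == "MLO"


class TestNipple:
    def test_cc_nipple_near_constructed_apex(self, symmetric_study):
        params, study, _ = symmetric_study
        bm = _segmented(study)
        nip = locate_nipple(bm, "CC")
        h = params.image_shape[0]
        apex = (h / 2.0, params.right.half_axes_px[1] + 3)  # bump tip
        assert np.hypot(nip.point[0] - apex[0], nip.point[1] - apex[1]) <= 3.0

    def test_mirrored_image_gives_mirrored_nipple(self, symmetric_study):
        _, study, _ = symmetric_study
        bm = _segmented(study)
        nip = locate_nipple(bm, "CC")
        w = study.right.shape[1]
        mirrored = MammogramImage(np.fliplr(remove_artifacts(study.right).pixels))
        nip_m = locate_nipple(segment_breast(mirrored), "CC")
        assert nip_m.point == (nip.point[0], w - 1 - nip.point[1])

    def test_equidistant_arc_ties_break_to_lowest_row(self):
        px = np.zeros((256, 256))
        px[60:197, :81] = 0.8  # rectangle: whole right edge is equidistant
        bm = segment_breast(MammogramImage(px))
        nip = locate_nipple(bm, "CC")
        assert nip.point == (60, 80)

    def test_degenerate_arc_raises(self, symmetric_study):
        _, study, _ = symmetric_study
        bm = _segmented(study)
        bm_small = replace(bm, arc=bm.arc[:5])
        with pytest.raises(ValueError, match="degenerate"):
            locate_nipple(bm_small, "CC")


class TestContrastStretch:
    def test_full_range_image_unchanged(self):
        px = np.linspace(0, 1, 64 * 64).reshape(64, 64)
        out = contrast_stretch(MammogramImage(px), 0, 100)
        np.testing.assert_allclose(out.pixels, px, atol=1e-12)

    def test_two_valued_image_maps_to_binary(self):
        px = np.full((64, 64), 0.4)
        px[::2] = 0.6
        out = contrast_stretch(MammogramImage(px), 0, 100)
        assert set(np.unique(out.pixels)) == {0.0, 1.0}

    def test_constant_image_is_noop(self):
        px = np.full((64, 64), 0.5)
        out = contrast_stretch(MammogramImage(px), 2, 98)
        np.testing.assert_array_equal(out.pixels, px)

    def test_invalid_percentiles_rejected(self):
        img = MammogramImage(np.random.default_rng(0).random((64, 64)))
        with pytest.raises(ValueError):
            contrast_stretch(img, 98, 2)


class TestDecorrelationStretch:
    def test_constant_image_unchanged_via_fallback(self):
        px = np.full((64, 64), 0.5)
        out = decorrelation_stretch(MammogramImage(px))
        np.testing.assert_array_equal(out.pixels, px)

    def test_output_range_within_unit_interval(self, symmetric_study):
        _, study, _ = symmetric_study
        out = decorrelation_stretch(remove_artifacts(study.right))
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0

    def test_band_interior_contrast_strictly_increased(self, symmetric_study):
        """The enhancement must widen the skin-band vs interior intensity gap."""
        _, study, _ = symmetric_study
        clean = remove_artifacts(study.right)
        bm = segment_breast(clean)
        nip = locate_nipple(bm, "CC")
        band = extract_skin_band(bm, segment_lower_quadrant(bm, nip), 3).mask
        interior = bm.mask & ~band
        enhanced = decorrelation_stretch(clean)
        gap_before = clean.pixels[band].mean() - clean.pixels[interior].mean()
        gap_after = enhanced.pixels[band].mean() - enhanced.pixels[interior].mean()
        assert gap_after > gap_before
        assert enhanced.pixels[bm.mask].var() >= clean.pixels[bm.mask].var()


class TestMirrorSymmetry:
    def test_horizontal_flip_mirrors_mask_and_chest_side(self, symmetric_study):
        _, study, _ = symmetric_study
        clean = remove_artifacts(study.right)
        bm = segment_breast(clean)
        bm_flip = segment_breast(MammogramImage(np.fliplr(clean.pixels)))
        np.testing.assert_array_equal(bm_flip.mask, np.fliplr(bm.mask))
        assert bm_flip.chest_side == "right"

    def test_pipeline_is_deterministic(self, symmetric_study):
        _, study, _ = symmetric_study
        bm1 = _segmented(study)
        bm2 = _segmented(study)
        np.testing.assert_array_equal(bm1.mask, bm2.mask)
        assert locate_nipple(bm1, "CC").point == locate_nipple(bm2, "CC").point
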