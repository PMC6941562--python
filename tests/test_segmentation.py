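"""Pixel classification: predicates, vectorized/naive equivalence, ROI, overlays."""

import numpy as np
import pytest

from amac import (ColorClass, ThresholdScheme, classify_pixel,
                  count_roi_classes, render_overlay, segment_section)
from amac.segmentation import _predicate

from conftest import random_rgb_image


class TestClassifyPixel:
    @pytest.mark.parametrize("rgb, expected", [
        ((255, 255, 255), ColorClass.BACKGROUND),   # near-white slide
        ((240, 235, 230), ColorClass.BACKGROUND),
        ((30, 30, 200), ColorClass.COLLAGEN),       # pure blue scar
        ((140, 140, 170), ColorClass.COLLAGEN),     # blue-gray gradient end
        ((150, 150, 155), ColorClass.COLLAGEN),     # gray band, low spread
        ((200, 40, 40), ColorClass.MUSCLE),         # red muscle
        ((220, 90, 90), ColorClass.MUSCLE),
        ((100, 180, 100), ColorClass.OTHER_TISSUE), # green-ish: no predicate
        ((10, 10, 10), ColorClass.OTHER_TISSUE),    # dark, below gray band
    ])
    def test_default_scheme_examples(self, rgb, expected, scheme):
        assert classify_pixel(rgb, scheme=scheme) is expected

    def test_transparent_pixel_is_background_regardless_of_color(self, scheme):
        assert classify_pixel((30, 30, 200), alpha=0, scheme=scheme) \
            is ColorClass.BACKGROUND
        assert classify_pixel((30, 30, 200), alpha=255, scheme=scheme) \
            is ColorClass.COLLAGEN

    @pytest.mark.parametrize("bad", [(-1, 0, 0), (0, 256, 0), (0, 0, 999)])
    def test_out_of_range_channel_rejected(self, bad, scheme):
        with pytest.raises(ValueError):
            classify_pixel(bad, scheme=scheme)

    def test_invalid_alpha_rejected(self, scheme):
        with pytest.raises(ValueError):
            classify_pixel((0, 0, 0), alpha=300, scheme=scheme)


class TestThresholdScheme:
    def test_rejects_bad_gray_bounds(self):
        with pytest.raises(ValueError):
            ThresholdScheme(gray_low=200, gray_high=90)

    def test_rejects_incomplete_precedence(self):
        with pytest.raises(ValueError):
            ThresholdScheme(precedence=(ColorClass.BACKGROUND,) * 4)

    def test_roundtrips_through_dict(self):
        s = ThresholdScheme(blue_margin=33, precedence=(
            ColorClass.COLLAGEN, ColorClass.BACKGROUND,
            ColorClass.MUSCLE, ColorClass.OTHER_TISSUE))
        assert ThresholdScheme.from_dict(s.to_dict()) == s


class TestSegmentSection:
    def test_uniform_white_image_is_all_background(self, scheme):
        img = np.full((10, 10, 3), 255, dtype=np.uint8)
        cm = segment_section(img, scheme)
        assert cm.counts == {ColorClass.BACKGROUND: 100, ColorClass.COLLAGEN: 0,
                             ColorClass.MUSCLE: 0, ColorClass.OTHER_TISSUE: 0}

    def test_painted_counts_match_paint_plan(self, scheme):
        flat = np.full((360, 3), 255, dtype=np.uint8)
        flat[:100] = (30, 30, 200)      # 100 blue
        flat[100:300] = (200, 40, 40)   # 200 red, 60 white remain
        cm = segment_section(flat.reshape(20, 18, 3), scheme)
        assert cm.counts[ColorClass.COLLAGEN] == 100
        assert cm.counts[ColorClass.MUSCLE] == 200
        assert cm.counts[ColorClass.BACKGROUND] == 60

    def test_counts_conservation_on_random_images(self, scheme, rng):
        for _ in range(5):
            img = random_rgb_image(rng)
            cm = segment_section(img, scheme)
            assert sum(cm.counts.values()) == img.shape[0] * img.shape[1]

    def test_vectorized_equals_naive_pixel_loop(self, scheme, rng):
        """Oracle equivalence: the array path reproduces classify_pixel."""
        for alpha in (False, True):
            img = random_rgb_image(rng, alpha=alpha)
            cm = segment_section(img, scheme)
            for i in range(img.shape[0]):
                for j in range(img.shape[1]):
                    a = int(img[i, j, 3]) if alpha else None
                    assert cm.labels[i, j] == classify_pixel(
                        img[i, j, :3], alpha=a, scheme=scheme)

    def test_determinism(self, scheme, rng):
        img = random_rgb_image(rng)
        a = segment_section(img, scheme)
        b = segment_section(img, scheme)
        assert np.array_equal(a.labels, b.labels)

    def test_precedence_permutation_changes_only_ambiguous_pixels(self, rng):
        base = ThresholdScheme()
        flipped = ThresholdScheme(precedence=(
            ColorClass.MUSCLE, ColorClass.COLLAGEN,
            ColorClass.BACKGROUND, ColorClass.OTHER_TISSUE))
        img = random_rgb_image(rng)
        la = segment_section(img, base).labels
        lb = segment_section(img, flipped).labels
        diff = np.argwhere(la != lb)
        for i, j in diff:
            r, g, b = (int(v) for v in img[i, j])
            n_match = sum(_predicate(c, r, g, b, None, base)
                          for c in ColorClass)
            assert n_match >= 2

    @pytest.mark.parametrize("bad", [
        np.zeros((0, 5, 3), dtype=np.uint8),
        np.zeros((5, 5), dtype=np.uint8),
        np.zeros((5, 5, 3), dtype=np.uint16),
    ])
    def test_rejects_malformed_images(self, bad, scheme):
        with pytest.raises(ValueError):
            segment_section(bad, scheme)


class TestRoiCounts:
    def test_full_roi_equals_section_counts(self, phantom_section, scheme):
        cm = segment_section(phantom_section.image, scheme)
        roi = np.ones(cm.labels.shape, dtype=bool)
        assert count_roi_classes(cm, roi) == cm.counts

    def test_empty_roi_is_all_zero(self, phantom_section, scheme):
        cm = segment_section(phantom_section.image, scheme)
        roi = np.zeros(cm.labels.shape, dtype=bool)
        assert all(v == 0 for v in count_roi_classes(cm, roi).values())

    def test_random_roi_matches_masked_pixel_loop(self, scheme, rng):
        img = random_rgb_image(rng, 32, 32)
        cm = segment_section(img, scheme)
        roi = rng.random((32, 32)) < 0.4
        got = count_roi_classes(cm, roi)
        brute = {c: 0 for c in ColorClass}
        for i in range(32):
            for j in range(32):
                if roi[i, j]:
                    brute[classify_pixel(img[i, j], scheme=scheme)] += 1
        assert got == brute

    def test_dimension_mismatch_rejected(self, phantom_section, scheme):
        cm = segment_section(phantom_section.image, scheme)
        with pytest.raises(ValueError):
            count_roi_classes(cm, np.ones((3, 3), dtype=bool))


class TestRenderOverlay:
    def test_excluded_classes_are_transparent(self, scheme):
        img = np.full((8, 8, 3), (200, 40, 40), dtype=np.uint8)  # all muscle
        cm = segment_section(img, scheme)
        ov = render_overlay(cm, [ColorClass.COLLAGEN])
        assert ov.shape == (8, 8, 4)
        assert (ov[..., 3] == 0).all()

    def test_opaque_pixel_count_equals_included_class_counts(
            self, phantom_section, scheme):
        cm = segment_section(phantom_section.image, scheme)
        ov = render_overlay(cm, [ColorClass.COLLAGEN, ColorClass.MUSCLE])
        opaque = int((ov[..., 3] == 255).sum())
        assert opaque == (cm.counts[ColorClass.COLLAGEN]
                          + cm.counts[ColorClass.MUSCLE])
        assert ((ov[..., 3] == 0) | (ov[..., 3] == 255)).all()

    def test_overlay_roundtrip_preserves_opaque_positions(
            self, phantom_section, scheme, tmp_path):
        import imageio.v3 as iio
        cm = segment_section(phantom_section.image, scheme)
        ov = render_overlay(cm, [ColorClass.COLLAGEN])
        p = tmp_path / "ov.png"
        iio.imwrite(p, ov)
        back = iio.imread(p)
        assert np.array_equal(back, ov)

    def test_empty_include_rejected(self, phantom_section, scheme):
        cm = segment_section(phantom_section.image, scheme)
        with pytest.raises(ValueError):
            render_overlay(cm, [])
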