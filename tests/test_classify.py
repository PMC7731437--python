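import csv

import numpy as np
import pytest
from PIL import Image

from quadratcover.classify import (
    ClassificationParams,
    ClassMasks,
    band_means,
    classify_gv,
    classify_image,
    classify_sdm,
    compute_cover,
    cover_csv_row,
    export_mask_png,
    masks_to_indexed,
    write_cover_csv,
)

from _oracles import oracle_classify
from conftest import norm_image


@pytest.fixture
def four_pixel_image():
    """2 x 2 image with pixels (R,G,B): (300,500,200), (800,800,800),
    (100,100,100), (100,100,100). Band means: (325, 375, 300)."""
    return norm_image(
        red=[[300, 800], [100, 100]],
        green=[[500, 800], [100, 100]],
        blue=[[200, 800], [100, 100]],
    )


class TestGVRule:
    @pytest.mark.parametrize(
        "pixel, expected",
        [
            ((100, 200, 100), True),   # both differences 100 > 60
            ((100, 160, 100), False),  # difference exactly 60: strict
            ((100, 161, 100), True),
            ((200, 100, 100), False),
        ],
    )
    def test_single_pixel_hand_cases(self, pixel, expected):
        r, g, b = pixel
        img = norm_image([[r]], [[g]], [[b]])
        assert classify_gv(img, 60.0, 60.0)[0, 0] == expected

    def test_thresholds_beyond_range_give_empty_mask(self, random_normalized):
        img = random_normalized()
        assert not classify_gv(img, 1024.0, 1024.0).any()

    def test_negative_thresholds_permitted(self):
        img = norm_image([[100]], [[90]], [[80]])
        assert classify_gv(img, -20.0, -20.0)[0, 0]


class TestBandMeans:
    def test_arithmetic_mean(self):
        img = norm_image(
            [[0, 1023], [0, 1023]], [[0, 1023], [0, 1023]], [[0, 1023], [0, 1023]]
        )
        m = band_means(img)
        assert m.mean_r == m.mean_g == m.mean_b == 511.5

    def test_means_include_gv_pixels_and_do_not_mutate(self, four_pixel_image):
        before = band_means(four_pixel_image)
        classify_image(four_pixel_image)
        after = band_means(four_pixel_image)
        assert before == after
        assert (before.mean_r, before.mean_g, before.mean_b) == (325.0, 375.0, 300.0)

    def test_matches_scalar_loop(self, random_normalized):
        img = random_normalized(9, 7)
        m = band_means(img)
        assert m.mean_r == pytest.approx(
            sum(float(v) for v in img.red.ravel()) / img.red.size, abs=1e-9
        )


class TestSDMRule:
    def test_worked_example_default_d(self, four_pixel_image):
        img = four_pixel_image
        gv = classify_gv(img, 60.0, 60.0)
        np.testing.assert_array_equal(gv, [[True, False], [False, False]])
        sdm = classify_sdm(img, gv, band_means(img), d=1.0)
        np.testing.assert_array_equal(sdm, [[False, True], [False, False]])

    def test_worked_example_d3_empty(self, four_pixel_image):
        img = four_pixel_image
        gv = classify_gv(img, 60.0, 60.0)
        sdm = classify_sdm(img, gv, band_means(img), d=3.0)
        assert not sdm.any()  # 800 < 3 * 325 = 975

    def test_identical_non_gv_pixels_never_sdm(self):
        # strict inequality v > v fails for every pixel
        img = norm_image(np.full((3, 3), 50.0), np.full((3, 3), 60.0), np.full((3, 3), 70.0))
        gv = np.zeros((3, 3), dtype=bool)
        assert not classify_sdm(img, gv, band_means(img), d=1.0).any()

    def test_gv_pixels_excluded_even_if_bright(self):
        img = norm_image([[100, 900]], [[100, 999]], [[100, 900]])
        gv = classify_gv(img, 60.0, 60.0)
        assert gv[0, 1]
        sdm = classify_sdm(img, gv, band_means(img), d=1.0)
        assert not sdm[0, 1]

    def test_shape_mismatch_rejected(self, four_pixel_image):
        with pytest.raises(ValueError, match="shape"):
            classify_sdm(
                four_pixel_image,
                np.zeros((3, 3), dtype=bool),
                band_means(four_pixel_image),
                d=1.0,
            )


class TestCover:
    def test_counting(self):
        gv = np.zeros((10, 10), dtype=bool)
        gv[:5, :5] = True  # 25 pixels
        masks = ClassMasks(gv=gv, sdm=np.zeros_like(gv), other=~gv)
        cover = compute_cover(masks)
        assert (cover.gv_pixels, cover.sdm_pixels) == (25, 0)
        assert (cover.gv_cover, cover.sdm_cover) == (25.0, 0.0)

    def test_all_gv(self):
        gv = np.ones((4, 4), dtype=bool)
        masks = ClassMasks(gv=gv, sdm=np.zeros_like(gv), other=np.zeros_like(gv))
        cover = compute_cover(masks)
        assert (cover.gv_cover, cover.sdm_cover) == (100.0, 0.0)

    def test_zero_pixel_image_is_an_error(self):
        empty = np.zeros((0, 0), dtype=bool)
        masks = ClassMasks(gv=empty, sdm=empty, other=empty)
        with pytest.raises(ValueError, match="zero-pixel"):
            compute_cover(masks)

    def test_overlapping_masks_rejected(self):
        m = np.ones((2, 2), dtype=bool)
        with pytest.raises(ValueError, match="disjoint"):
            ClassMasks(gv=m, sdm=m, other=~m)


class TestPipeline:
    def test_worked_example_composition(self, four_pixel_image):
        _, cover = classify_image(four_pixel_image)
        assert (cover.gv_cover, cover.sdm_cover) == (25.0, 25.0)

    def test_matches_per_pixel_reference(self, random_normalized, rng):
        for _ in range(10):
            h, w = rng.integers(2, 65, size=2)
            img = random_normalized(int(h), int(w))
            g1, g2 = rng.uniform(-50, 300, size=2)
            d = rng.uniform(0.4, 2.5)
            masks, _ = classify_image(img, ClassificationParams(g1=g1, g2=g2, d=d))
            ref_gv, ref_sdm = oracle_classify(img.red, img.green, img.blue, g1, g2, d)
            np.testing.assert_array_equal(masks.gv, ref_gv)
            np.testing.assert_array_equal(masks.sdm, ref_sdm)

    def test_masks_partition_every_pixel(self, random_normalized):
        for params in [ClassificationParams(), ClassificationParams(g1=-100, g2=-100, d=0.1)]:
            masks, _ = classify_image(random_normalized(), params)
            assert not (masks.gv & masks.sdm).any()
            assert ((masks.gv | masks.sdm | masks.other)).all()

    def test_cover_monotone_in_each_parameter(self, random_normalized):
        img = random_normalized(24, 24)
        for vary in ("g1", "g2"):
            covers = [
                classify_image(img, ClassificationParams(**{vary: g}))[1].gv_cover
                for g in np.linspace(-100, 400, 10)
            ]
            assert all(a >= b for a, b in zip(covers, covers[1:]))
        sdm_covers = [
            classify_image(img, ClassificationParams(d=d))[1].sdm_cover
            for d in np.linspace(0.3, 2.5, 10)
        ]
        assert all(a >= b for a, b in zip(sdm_covers, sdm_covers[1:]))

    def test_cover_invariant_under_block_replication(self, random_normalized):
        img = random_normalized(8, 8)
        _, small = classify_image(img)
        big = norm_image(
            *(np.repeat(np.repeat(b, 3, axis=0), 3, axis=1) for b in img.bands().values())
        )
        _, scaled = classify_image(big)
        assert small.gv_cover == scaled.gv_cover
        assert small.sdm_cover == scaled.sdm_cover

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ClassificationParams(d=0)
        with pytest.raises(ValueError):
            ClassificationParams(g1=float("nan"))


class TestExports:
    def test_mask_png_values_are_class_codes(self, tmp_path, four_pixel_image):
        masks, _ = classify_image(four_pixel_image)
        np.testing.assert_array_equal(masks_to_indexed(masks), [[1, 2], [0, 0]])
        path = export_mask_png(masks, tmp_path / "mask.png")
        back = np.asarray(Image.open(path))
        np.testing.assert_array_equal(back, [[1, 2], [0, 0]])

    def test_cover_csv_schema_and_formatting(self, tmp_path, four_pixel_image):
        _, cover = classify_image(four_pixel_image)
        row = cover_csv_row("quadrat_01.png", cover, ClassificationParams())
        path = write_cover_csv([row], tmp_path / "covers.csv")
        with open(path) as fh:
            rows = list(csv.DictReader(fh))
        assert rows[0]["image"] == "quadrat_01.png"
        assert rows[0]["gv_cover_pct"] == "25.0000"
        assert rows[0]["sdm_cover_pct"] == "25.0000"
        assert rows[0]["g1"] == "60" and rows[0]["d"] == "1"
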