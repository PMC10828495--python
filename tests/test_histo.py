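"""Fibrosis color filtering, morphometry and renal score tables."""

import numpy as np
import pandas as pd
import pytest

from ucmp.histo import (
    FilterConfig,
    NoTissueError,
    PixelClass,
    RenalScorePanel,
    cell_metrics,
    classify_pixel,
    classify_pixels,
    fibrosis_fraction,
    scores_to_contingency,
    summarize_diameters,
)
from ucmp.synth import ImageSpec, gen_cell_masks, gen_psfg_image


def solid(h, w, color):
    return np.tile(np.array(color, dtype=np.uint8), (h, w, 1))


class TestClassification:
    @pytest.mark.parametrize(
        "rgb, expected",
        [
            ((255, 255, 255), PixelClass.EXCLUDED),  # empty slide
            ((210, 210, 215), PixelClass.EXCLUDED),  # light-gray debris
            ((200, 30, 40), PixelClass.RED),         # stained collagen
            ((40, 160, 60), PixelClass.GREEN_TISSUE),
            ((10, 10, 10), PixelClass.GREEN_TISSUE),  # dark but not gray-excluded
        ],
    )
    def test_default_classes(self, rgb, expected):
        assert classify_pixel(*rgb) == expected

    def test_exclusion_wins_over_red(self):
        # a pale pinkish near-white pixel: hue in the red window but
        # bright/low-spread enough to be excluded first
        cfg = FilterConfig(white_gray_min_channel=180, white_gray_max_spread=25,
                           min_saturation=0.0, luminance_low=0.0, luminance_high=1.0)
        assert classify_pixel(205, 185, 190, cfg) == PixelClass.EXCLUDED

    def test_counts_partition_image(self, small_psfg):
        img, _ = small_psfg
        codes = classify_pixels(img)
        counts = [(codes == c).sum() for c in PixelClass]
        assert sum(counts) == img.shape[0] * img.shape[1]

    def test_hue_window_wraparound(self):
        cfg = FilterConfig(red_hue_low=330.0, red_hue_high=25.0)
        # hue ~ 350 (wrap side) and hue ~ 10 both red; hue ~ 60 is not
        assert classify_pixel(200, 30, 58, cfg) == PixelClass.RED
        assert classify_pixel(200, 58, 30, cfg) == PixelClass.RED
        assert classify_pixel(200, 200, 30, cfg) == PixelClass.GREEN_TISSUE


class TestFibrosisFraction:
    def test_all_green_is_zero(self):
        res = fibrosis_fraction(solid(32, 32, (40, 160, 60)))
        assert res.fraction == 0.0
        assert res.n_red == 0

    def test_half_red_half_green_with_white_border(self):
        img = np.concatenate([solid(16, 32, (200, 30, 40)),
                              solid(16, 32, (40, 160, 60))])
        padded = np.pad(img, ((8, 8), (8, 8), (0, 0)), constant_values=255)
        assert fibrosis_fraction(img).fraction == 0.5
        assert fibrosis_fraction(padded).fraction == 0.5

    def test_white_padding_bit_identical(self, small_psfg):
        img, _ = small_psfg
        base = fibrosis_fraction(img)
        padded = np.pad(img, ((20, 20), (20, 20), (0, 0)), constant_values=255)
        res = fibrosis_fraction(padded)
        assert res.fraction == base.fraction
        assert (res.n_red, res.n_green) == (base.n_red, base.n_green)

    def test_tiled_equals_whole(self, small_psfg):
        img, _ = small_psfg
        whole = fibrosis_fraction(img)
        # tile size does not divide the image evenly on purpose
        tiled = fibrosis_fraction(img, tile_shape=(100, 70))
        assert tiled == whole

    def test_recovers_ground_truth(self, small_psfg):
        img, truth = small_psfg
        res = fibrosis_fraction(img)
        assert res.fraction == pytest.approx(truth.true_fraction, abs=0.01)

    @pytest.mark.parametrize("target", [0.0, 0.05, 0.1, 0.3])
    def test_recovery_across_fractions(self, target):
        img, truth = gen_psfg_image(ImageSpec(width=192, height=192,
                                              target_fibrosis_fraction=target,
                                              seed=11))
        res = fibrosis_fraction(img)
        assert abs(res.fraction - truth.true_fraction) <= 0.01
        assert truth.true_fraction == pytest.approx(target, abs=0.01)

    def test_no_tissue_raises(self):
        with pytest.raises(NoTissueError):
            fibrosis_fraction(solid(16, 16, (255, 255, 255)))

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            fibrosis_fraction(np.zeros((0, 4, 3), dtype=np.uint8))


class TestCellMetrics:
    def test_square_area(self):
        mask = np.zeros((20, 20), dtype=np.int32)
        mask[5:15, 5:15] = 1
        (m,) = cell_metrics(mask, pixel_size=1.0)
        assert m.area == pytest.approx(100.0)
        assert m.transverse_diameter == pytest.approx(10.0, rel=0.1)

    def test_disk_area_and_perimeter(self):
        yy, xx = np.mgrid[0:40, 0:40]
        mask = (((yy - 20) ** 2 + (xx - 20) ** 2) <= 100).astype(np.int32)
        (m,) = cell_metrics(mask, pixel_size=1.0)
        assert m.area == pytest.approx(np.pi * 100, rel=0.02)
        assert m.perimeter == pytest.approx(2 * np.pi * 10, rel=0.08)
        # rasterized width of an r=10 disk is 21 px, so allow ~1 px slack
        assert m.transverse_diameter == pytest.approx(20.0, rel=0.08)

    def test_isoperimetric_bound(self):
        mask, _ = gen_cell_masks(20, seed=5)
        for m in cell_metrics(mask, pixel_size=0.5):
            equiv_d = 2 * np.sqrt(m.area / np.pi)
            assert m.perimeter >= np.pi * equiv_d * 0.98  # discretization slack

    def test_hundred_cells_match_truth(self):
        mask, truth = gen_cell_masks(100, seed=3)
        metrics = cell_metrics(mask, pixel_size=0.5)
        assert len(metrics) == 100
        assert sorted(m.label for m in metrics) == list(range(1, 101))
        mean_meas = np.mean([m.area for m in metrics])
        assert mean_meas == pytest.approx(truth["area"].mean(), rel=0.02)

    def test_area_equals_pixel_count_oracle(self):
        mask, _ = gen_cell_masks(10, seed=1)
        ps = 0.7
        for m in cell_metrics(mask, pixel_size=ps):
            assert m.area == pytest.approx((mask == m.label).sum() * ps**2)

    def test_nucleus_point_outside_cell_rejected(self):
        mask = np.zeros((20, 20), dtype=np.int32)
        mask[5:15, 5:15] = 1
        with pytest.raises(ValueError):
            cell_metrics(mask, 1.0, nucleus_points={1: (0, 0)})
        with pytest.raises(ValueError):
            cell_metrics(mask, 1.0, nucleus_points={2: (7, 7)})  # absent label


class TestDiameters:
    def test_examples(self):
        assert summarize_diameters([10, 10, 10]) == (10, 0)
        mean, sem = summarize_diameters([8, 12])
        assert (mean, sem) == (10, pytest.approx(2.0))

    def test_oracle_equivalence(self, rng):
        vals = rng.uniform(40, 120, size=10)
        mean, sem = summarize_diameters(vals)
        assert mean == pytest.approx(sum(vals) / 10)
        sd = np.sqrt(sum((v - mean) ** 2 for v in vals) / 9)
        assert sem == pytest.approx(sd / np.sqrt(10))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_diameters([])


class TestScores:
    def test_all_grade_zero(self):
        panels = [RenalScorePanel(0, 0, 0, 0) for _ in range(4)]
        groups = ["Sham", "Sham", "CKD", "CKD"]
        table = scores_to_contingency(panels, groups, "arteriole_hyalinosis",
                                      grouping={"Sham": "Sham", "CKD": "CKD"})
        assert table.shape == (2, 1)
        assert (table.to_numpy() == [[2], [2]]).all()

    def test_pooling_and_counts_match_hand_count(self):
        grades = [0, 1, 2, 1, 0, 2, 2, 1]
        arms = ["Sham", "Sham", "CKD", "CKD", "CKD+D1", "CKD+D1", "CKD+D2", "CKD+D2"]
        panels = [RenalScorePanel(0, g, 0, 0) for g in grades]
        grouping = {"Sham": "untreated", "CKD": "untreated",
                    "CKD+D1": "treated", "CKD+D2": "treated"}
        table = scores_to_contingency(panels, arms, "tubular_dilatation", grouping)
        # hand count: untreated grades [0,1,2,1], treated [0,2,2,1]
        assert table.loc["untreated"].tolist() == [1, 2, 1]
        assert table.loc["treated"].tolist() == [1, 1, 2]

    def test_grade_validation(self):
        with pytest.raises(ValueError):
            RenalScorePanel(2, 0, 0, 0)  # hypertrophy scale is 0/1

    def test_unknown_criterion(self):
        with pytest.raises(ValueError):
            scores_to_contingency([RenalScorePanel(0, 0, 0, 0)], ["Sham"],
                                  "nonexistent", {"Sham": "Sham"})
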