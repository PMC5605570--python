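"""Adaptive-threshold DCX quantification against hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest

import dgquant.histo as histo
from dgquant.config import GeneratorConfig
from dgquant.core import SectionImage
from dgquant.synth import generate_section_images


def _image(pixels, masks, pixel_size=1.0, **kw):
    return SectionImage(pixels=np.asarray(pixels, dtype=np.uint8),
                        masks=np.asarray(masks, dtype=np.uint8),
                        pixel_size_um=pixel_size, region="dorsal", **kw)


@pytest.mark.parametrize("rgb, expected", [
    ((255, 255, 255), 255),
    ((0, 0, 0), 0),
    ((100, 150, 200), 141),  # round(0.299*100 + 0.587*150 + 0.114*200)
])
def test_to_grayscale_luminance(rgb, expected):
    img = np.full((2, 2, 3), rgb, dtype=np.uint8)
    assert (histo.to_grayscale(img) == expected).all()


def test_to_grayscale_rejects_wrong_channels():
    with pytest.raises(ValueError):
        histo.to_grayscale(np.zeros((4, 4)))


class TestComputeThreshold:
    def test_uniform_roi_zero_variance(self):
        img = _image(np.full((4, 4), 200), np.full((4, 4), 2))
        res = histo.compute_threshold(img)
        assert (res.mean_gray, res.sd_gray, res.threshold) == (200, 0, 200)

    def test_two_pixel_sample_sd(self):
        # {90, 110}: mean 100, sample SD sqrt(2)*10, threshold 100-2*14.142
        masks = np.zeros((1, 4), dtype=int)
        masks[0, :2] = 2
        img = _image([[90, 110, 0, 0]], masks)
        res = histo.compute_threshold(img)
        assert res.mean_gray == pytest.approx(100.0)
        assert res.sd_gray == pytest.approx(14.1421, abs=1e-4)
        assert res.threshold == pytest.approx(71.7157, abs=1e-4)

    def test_population_sd_option(self):
        masks = np.zeros((1, 4), dtype=int)
        masks[0, :2] = 2
        img = _image([[90, 110, 0, 0]], masks)
        res = histo.compute_threshold(img, ddof=0)
        assert res.sd_gray == pytest.approx(10.0)
        assert res.threshold == pytest.approx(80.0)  # mean - 2 SD

    def test_tiny_roi_rejected(self):
        masks = np.zeros((2, 2), dtype=int)
        masks[0, 0] = 2
        with pytest.raises(histo.InsufficientRoiError):
            histo.compute_threshold(_image(np.zeros((2, 2)), masks))


class TestMeasureArea:
    def test_nothing_below_threshold(self):
        img = _image(np.full((3, 3), 180), np.ones((3, 3)))
        dcx, gcl = histo.measure_dcx_area(img, 130.0)
        assert dcx == 0.0
        assert gcl == 9.0

    def test_strict_inequality_at_boundary(self):
        img = _image([[130, 129]], [[1, 1]])
        dcx, _ = histo.measure_dcx_area(img, 130.0)
        assert dcx == 1.0  # only the 129 pixel counts

    def test_pixel_size_scaling(self):
        pix = np.array([[40, 180], [180, 180]])
        a1 = histo.measure_dcx_area(_image(pix, np.ones((2, 2)), 1.0), 130)
        a2 = histo.measure_dcx_area(_image(pix, np.ones((2, 2)), 0.5), 130)
        assert a2[0] == pytest.approx(a1[0] / 4)
        assert a2[1] == pytest.approx(a1[1] / 4)

    def test_exact_on_generated_ground_truth(self):
        cfg = GeneratorConfig(seed=3, bg_sd_gray=0.0, pos_sd_gray=0.0)
        animal = _ihc_animal(cfg)
        frames = generate_section_images(animal, cfg)
        img = frames[0]
        dcx, gcl = histo.measure_dcx_area(img, 130.0)
        assert dcx / gcl == pytest.approx(img.truth["true_fraction"])
        assert dcx == img.truth["positive_px"] * cfg.pixel_size_um_dcx ** 2


def _ihc_animal(cfg):
    from dgquant.synth import generate_cohort
    return next(a for a in generate_cohort(cfg) if a.arm == "IHC")


class TestAggregate:
    def _table(self, rows):
        return pd.DataFrame(
            [{"animal_id": "a1", "region": "dorsal", "section_index": i,
              "frame_index": 0, "threshold": 100.0,
              "dcx_area_um2": d, "gcl_area_um2": g}
             for i, (d, g) in enumerate(rows)])

    def test_pooled_ratio_not_mean_of_ratios(self):
        # (10,100) and (30,300): pooled 40/400 = 0.1, mean of ratios 0.2
        quants = histo.aggregate_dcx(self._table([(10, 100), (30, 300)]))
        assert quants[0].normalized == pytest.approx(0.1)

    def test_single_section(self):
        quants = histo.aggregate_dcx(self._table([(30, 300)]))
        assert quants[0].normalized == pytest.approx(0.1)

    def test_zero_dcx(self):
        quants = histo.aggregate_dcx(self._table([(0, 100), (0, 50)]))
        assert quants[0].normalized == 0.0

    def test_zero_gcl_rejected(self):
        with pytest.raises(histo.UndefinedRatioError):
            histo.aggregate_dcx(self._table([(0, 0)]))

    def test_intermediate_region_excluded_by_default(self):
        tbl = self._table([(10, 100)])
        tbl.loc[1] = ["a1", "intermediate", 0, 0, 100.0, 50, 100]
        quants = histo.aggregate_dcx(tbl)
        assert [q.region for q in quants] == ["dorsal"]


class TestEstimatorProperties:
    def test_threshold_ignores_stain_outside_clean_roi(self):
        cfg = GeneratorConfig(seed=5)
        animal = _ihc_animal(cfg)
        img = generate_section_images(animal, cfg)[0]
        res = histo.compute_threshold(img)
        # blank out all stain outside the clean ROI: threshold unchanged
        blank = img.pixels.copy()
        blank[~img.clean_mask] = 200
        res2 = histo.compute_threshold(SectionImage(
            pixels=blank, masks=img.masks, pixel_size_um=1.0,
            region=img.region))
        assert res2.threshold == res.threshold

    def test_traversal_order_independence(self):
        cfg = GeneratorConfig(seed=5)
        frames = generate_section_images(_ihc_animal(cfg), cfg)
        fwd = histo.quantify_animal(frames)
        rev = histo.quantify_animal(frames[::-1])
        key = ["region", "section_index"]
        merged = fwd.merge(rev, on=key, suffixes=("_f", "_r"))
        assert np.allclose(merged["dcx_area_um2_f"],
                           merged["dcx_area_um2_r"])

    def test_noise_free_estimate_matches_truth(self):
        """With sigma_bg = 0 the threshold separates stain perfectly."""
        cfg = GeneratorConfig(seed=9, bg_sd_gray=0.0, pos_sd_gray=0.0)
        animal = _ihc_animal(cfg)
        frames = generate_section_images(animal, cfg)
        table = histo.quantify_animal(frames, per_frame_threshold=True)
        truth = sum(f.truth["positive_px"] for f in frames) \
            / sum(f.truth["gcl_px"] for f in frames)
        quants = histo.aggregate_dcx(table)
        pooled = (sum(q.dcx_area_um2 for q in quants)
                  / sum(q.gcl_area_um2 for q in quants))
        assert abs(pooled - truth) < 0.005
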