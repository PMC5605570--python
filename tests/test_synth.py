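"""Generator contracts: determinism, ground-truth sidecars, expectations."""

import numpy as np
import pytest

from dgquant.config import GeneratorConfig, InvalidConfigError
from dgquant.synth import (generate_activity_and_expression,
                           generate_bdnf_images, generate_cohort,
                           generate_outlines, generate_section_images)
from dgquant.synth.seeding import ln_noise, rng_for


def _ihc_animal(cfg, treatment=None):
    for a in generate_cohort(cfg):
        if a.arm == "IHC" and treatment in (None, a.treatment):
            return a
    raise AssertionError


class TestDeterminism:
    def test_dcx_frames_bit_identical(self):
        cfg = GeneratorConfig(seed=31)
        animal = _ihc_animal(cfg)
        f1 = generate_section_images(animal, cfg)
        f2 = generate_section_images(animal, cfg)
        assert len(f1) == len(f2)
        for a, b in zip(f1, f2):
            assert np.array_equal(a.pixels, b.pixels)
            assert np.array_equal(a.masks, b.masks)
            assert a.truth == b.truth

    def test_tables_identical(self):
        cfg = GeneratorConfig(seed=31)
        cohort = generate_cohort(cfg)
        b1 = generate_activity_and_expression(cohort, cfg)
        b2 = generate_activity_and_expression(cohort, cfg)
        assert b1.expression.equals(b2.expression)
        assert b1.standards.equals(b2.standards)
        assert b1.truth_distance.equals(b2.truth_distance)

    def test_different_seeds_differ(self):
        c1, c2 = GeneratorConfig(seed=31), GeneratorConfig(seed=32)
        f1 = generate_section_images(_ihc_animal(c1), c1)
        f2 = generate_section_images(_ihc_animal(c2), c2)
        assert not np.array_equal(f1[0].pixels, f2[0].pixels)


class TestDcxFrames:
    def test_section_count_and_truth_fields(self):
        cfg = GeneratorConfig(seed=33)
        frames = generate_section_images(_ihc_animal(cfg), cfg)
        by_region = {}
        for f in frames:
            by_region.setdefault(f.region, []).append(f)
        assert set(by_region) == {"dorsal", "ventral"}
        for region_frames in by_region.values():
            assert 4 <= len(region_frames) <= 6
        for f in frames:
            gcl = int(f.gcl_mask.sum())
            assert f.truth["gcl_px"] == gcl
            assert f.truth["true_fraction"] == f.truth["positive_px"] / gcl

    def test_zero_fraction_gives_empty_truth(self):
        cfg = GeneratorConfig(seed=33)
        cfg.dcx_fraction_control = {"dorsal": 0.0, "ventral": 0.0}
        frames = generate_section_images(_ihc_animal(cfg), cfg)
        assert all(f.truth["positive_px"] == 0 for f in frames)
        # no stained pixel anywhere in the GCL
        for f in frames:
            assert f.pixels[f.gcl_mask].min() > 100

    def test_clean_roi_is_stain_free(self):
        cfg = GeneratorConfig(seed=34)
        for f in generate_section_images(_ihc_animal(cfg), cfg):
            assert f.pixels[f.clean_mask].min() > 100

    def test_impossible_fraction_rejected(self):
        cfg = GeneratorConfig(seed=33)
        cfg.dcx_fraction_control["dorsal"] = 0.9  # 0.9 * 1.4 > 1
        with pytest.raises(InvalidConfigError):
            generate_section_images(_ihc_animal(GeneratorConfig(seed=33)),
                                    cfg)

    def test_truth_fold_in_expectation(self):
        """Mean E/C truth-fraction ratio matches the configured fold."""
        cfg = GeneratorConfig(seed=35)
        rng = rng_for(cfg.seed, "mc")
        n = 400
        noise_e = np.array([ln_noise(rng, cfg.dcx_animal_sigma)
                            for _ in range(n)])
        noise_c = np.array([ln_noise(rng, cfg.dcx_animal_sigma)
                            for _ in range(n)])
        base = cfg.dcx_fraction_control["dorsal"]
        fold = cfg.dcx_fold_enriched["dorsal"]
        e = base * fold * noise_e
        c = base * noise_c
        ratio = e.mean() / c.mean()
        sem = ratio * np.sqrt(noise_e.std() ** 2 / n
                              + noise_c.std() ** 2 / n)
        assert abs(ratio - fold) < 3 * sem


class TestBdnfFrames:
    def test_site_truth_and_ventral_excess(self):
        cfg = GeneratorConfig(seed=36)
        frames = generate_bdnf_images(_ihc_animal(cfg), cfg)
        dorsal = next(f for f in frames if f.region == "dorsal")
        ventral = next(f for f in frames if f.region == "ventral")
        for site, od in dorsal.truth["site_od"].items():
            assert ventral.truth["site_od"][site] == pytest.approx(
                od + cfg.bdnf_rod_ventral_excess)
        od = dorsal.truth["site_od"]
        assert od["hilus"] < od["infrapyramidal"] < od["suprapyramidal"]
        assert od["suprapyramidal"] == pytest.approx(od["mossy_fibers"],
                                                     abs=0.02)

    def test_zero_od_is_white(self):
        cfg = GeneratorConfig(seed=36, bdnf_pixel_gray_sd=0.0,
                              bdnf_background_od_range=(0.0, 0.0))
        cfg.bdnf_site_od_dorsal = {s: 0.0
                                   for s in cfg.bdnf_site_od_dorsal}
        frames = generate_bdnf_images(_ihc_animal(cfg), cfg)
        img = frames[0]
        assert img.pixels[img.masks >= 10].min() == 255


class TestOutlines:
    def test_spacing_follows_protocol(self):
        cfg = GeneratorConfig(seed=37)
        outlines, _ = generate_outlines(_ihc_animal(cfg), cfg)
        for o in outlines:
            expected = 480.0 if o.region == "dorsal" else 240.0
            assert o.spacing_to_next_um == expected

    def test_truth_volume_folds_in_expectation(self):
        cfg = GeneratorConfig(seed=38)
        e_vols, c_vols = [], []
        for seed in range(200):
            c2 = GeneratorConfig(seed=seed)
            cohort = generate_cohort(c2)
            e = next(a for a in cohort if a.arm == "IHC"
                     and a.treatment == "E")
            c = next(a for a in cohort if a.arm == "IHC"
                     and a.treatment == "C")
            _, te = generate_outlines(e, c2)
            _, tc = generate_outlines(c, c2)
            e_vols.append(te[("dorsal", "DG")] + te[("dorsal", "CA")])
            c_vols.append(tc[("dorsal", "DG")] + tc[("dorsal", "CA")])
        e_vols, c_vols = np.array(e_vols), np.array(c_vols)
        ratio = e_vols.mean() / c_vols.mean()
        sem = ratio * np.sqrt(
            (e_vols.std() / e_vols.mean()) ** 2 / 200
            + (c_vols.std() / c_vols.mean()) ** 2 / 200)
        assert abs(ratio - (1 + cfg.volume_effect_dorsal)) < 3 * sem


class TestExpressionTruth:
    def test_ratio_targets_in_expectation(self):
        """Cohort-mean true ratios hit configured folds within 3 SEM."""
        dorsal_e, dorsal_c = [], []
        for seed in range(50):
            cfg = GeneratorConfig(seed=seed)
            cohort = generate_cohort(cfg)
            behav = generate_activity_and_expression(cohort, cfg)
            truth = behav.truth_expression
            prot = truth[(truth.modality == "protein")
                         & (truth.region == "dorsal")]
            tmap = {a.animal_id: a.treatment for a in cohort}
            tr = prot.assign(t=prot.animal_id.map(tmap))
            dorsal_e.append(tr[tr.t == "E"]["ratio"].mean())
            dorsal_c.append(tr[tr.t == "C"]["ratio"].mean())
        ratio = np.mean(dorsal_e) / np.mean(dorsal_c)
        cfg = GeneratorConfig()
        sem = ratio * np.sqrt(np.var(dorsal_e) / np.mean(dorsal_e) ** 2
                              + np.var(dorsal_c) / np.mean(dorsal_c) ** 2) \
            / np.sqrt(50)
        assert abs(ratio - cfg.protein_fold["dorsal"]) < 3 * sem
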