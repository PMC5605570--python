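"""Synthetic DAB-stained section frames with exact pixel-level ground truth.

DCX frames emulate a 20x grayscale capture of the granule cell layer: a
bright tissue background (Gaussian gray values), a GCL band mask containing
a stain-free clean-ROI rectangle, and dark DCX-positive structures rendered
as soma disks and dendrite strokes.  The positive mask is trimmed or topped
up pixel by pixel so the stained fraction of the GCL equals the recorded
ground truth exactly, making the adaptive-threshold estimator scorable
without segmentation ambiguity.

BDNF frames emulate a 10x capture for densitometry: four rectangular
sampling-site ROIs (suprapyramidal and infrapyramidal blades, hilus, mossy
fibers) plus a corpus-callosum ROI, with gray values encoding a configured
true optical density per site on top of a shared per-section background OD
that the corpus-callosum correction is meant to remove.

The synthetic geometry is schematic, not an anatomical model of the dentate
gyrus; it exists to give every intensity-based estimator a known truth.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage.draw import disk, line

from dgquant.config import (BDNF_SITES, MASK_CLEAN_ROI, MASK_CORPUS_CALLOSUM,
                            MASK_GCL, MASK_SITE, GeneratorConfig,
                            InvalidConfigError)
from dgquant.core import AnimalRecord, SectionImage
from dgquant.synth.seeding import ln_noise, rng_for

__all__ = ["generate_section_images", "generate_bdnf_images"]


def _dcx_masks(shape: tuple[int, int]) -> np.ndarray:
    """GCL band with an embedded stain-free clean-ROI rectangle."""
    h, w = shape
    masks = np.zeros(shape, dtype=np.uint8)
    top, bottom = int(0.375 * h), int(0.625 * h)
    masks[top:bottom, :] = MASK_GCL
    r0 = top + (bottom - top) // 5
    r1 = r0 + max((bottom - top) // 2, 2)
    c0, c1 = int(0.05 * w), int(0.05 * w) + max(w // 8, 2)
    masks[r0:r1, c0:c1] = MASK_CLEAN_ROI
    return masks


def _stain_mask(rng: np.random.Generator, placeable: np.ndarray,
                k: int) -> np.ndarray:
    """Binary positive mask with exactly ``k`` pixels inside ``placeable``.

    Soma disks and dendrite strokes are stamped at random until the target
    count is exceeded, then the excess is removed pixel by pixel (any
    residual shortfall from crowded geometry is topped up with scattered
    single pixels), keeping the true positive count exact.
    """
    shape = placeable.shape
    canvas = np.zeros(shape, dtype=bool)
    if k == 0:
        return canvas
    n_placeable = int(placeable.sum())
    if k > n_placeable:
        raise InvalidConfigError(
            f"cannot place {k} positive pixels in {n_placeable} available")
    rows, cols = np.nonzero(placeable)
    count = 0
    for _ in range(50 * max(k // 10, 1)):
        if count >= k:
            break
        i = rng.integers(rows.size)
        r, c = int(rows[i]), int(cols[i])
        if rng.random() < 0.7:  # soma
            rr, cc = disk((r, c), int(rng.integers(2, 5)), shape=shape)
        else:  # dendrite stroke
            ang = rng.uniform(0, np.pi)
            length = int(rng.integers(6, 15))
            r2 = int(np.clip(r + length * np.sin(ang), 0, shape[0] - 1))
            c2 = int(np.clip(c + length * np.cos(ang), 0, shape[1] - 1))
            rr, cc = line(r, c, r2, c2)
        sel = placeable[rr, cc] & ~canvas[rr, cc]
        canvas[rr[sel], cc[sel]] = True
        count += int(sel.sum())
    if count > k:
        on_r, on_c = np.nonzero(canvas)
        drop = rng.choice(on_r.size, size=count - k, replace=False)
        canvas[on_r[drop], on_c[drop]] = False
    elif count < k:
        free = placeable & ~canvas
        fr, fc = np.nonzero(free)
        add = rng.choice(fr.size, size=k - count, replace=False)
        canvas[fr[add], fc[add]] = True
    return canvas


def _render(rng: np.random.Generator, positive: np.ndarray,
            cfg: GeneratorConfig) -> np.ndarray:
    gray = rng.normal(cfg.bg_mean_gray, cfg.bg_sd_gray, positive.shape)
    n_pos = int(positive.sum())
    if n_pos:
        gray[positive] = rng.normal(cfg.pos_mean_gray, cfg.pos_sd_gray, n_pos)
    return np.clip(np.floor(gray + 0.5), 0, 255).astype(np.uint8)


def generate_section_images(animal: AnimalRecord,
                            config: GeneratorConfig) -> list[SectionImage]:
    """DCX frames for one IHC-arm animal, dorsal and ventral.

    Per region, 4-6 serial sections are emitted (one montage frame each).
    The per-frame true stained fraction is the configured control fraction,
    times the enrichment fold for E animals, times between-animal and
    between-frame lognormal variation; it is stored in ``truth`` together
    with the exact positive-pixel count.
    """
    if animal.arm != "IHC":
        raise ValueError(f"animal {animal.animal_id} is not in the IHC arm")
    config.validate()
    if config.pos_mean_gray >= config.bg_mean_gray - 2 * config.bg_sd_gray:
        raise InvalidConfigError(
            "stained-pixel gray must lie below the background mean - 2 SD "
            "for the adaptive threshold to be able to separate them")
    rng = rng_for(config.seed, "dcx", animal.animal_id)
    masks = _dcx_masks(config.frame_shape)
    gcl_count = int(((masks == MASK_GCL) | (masks == MASK_CLEAN_ROI)).sum())
    placeable = masks == MASK_GCL  # the clean ROI stays stain-free
    max_frac = 0.9 * placeable.sum() / gcl_count
    frames = []
    for region in ("dorsal", "ventral"):
        base = config.dcx_fraction_control[region]
        if animal.treatment == "E":
            base *= config.dcx_fold_enriched[region]
        animal_frac = base * ln_noise(rng, config.dcx_animal_sigma)
        n_sections = int(rng.integers(config.dcx_sections_min,
                                      config.dcx_sections_max + 1))
        for section in range(n_sections):
            frac = animal_frac * ln_noise(rng, config.dcx_frame_sigma)
            frac = min(frac, max_frac)
            k = int(round(frac * gcl_count))
            positive = _stain_mask(rng, placeable, k)
            pixels = _render(rng, positive, config)
            frames.append(SectionImage(
                pixels=pixels, masks=masks.copy(),
                pixel_size_um=config.pixel_size_um_dcx, region=region,
                animal_id=animal.animal_id, section_index=section,
                truth={"true_fraction": k / gcl_count, "positive_px": k,
                       "gcl_px": gcl_count, "animal_fraction": animal_frac}))
    return frames


# ---------------------------------------------------------------------------
# BDNF densitometry frames

def _bdnf_masks(shape: tuple[int, int]) -> tuple[np.ndarray, dict]:
    h, w = shape
    masks = np.zeros(shape, dtype=np.uint8)
    side = max(h // 6, 4)
    spots = {
        "suprapyramidal": (int(0.15 * h), int(0.15 * w)),
        "infrapyramidal": (int(0.60 * h), int(0.15 * w)),
        "hilus": (int(0.38 * h), int(0.45 * w)),
        "mossy_fibers": (int(0.60 * h), int(0.70 * w)),
        "cc": (int(0.06 * h), int(0.70 * w)),
    }
    boxes = {}
    for name, (r, c) in spots.items():
        label = MASK_CORPUS_CALLOSUM if name == "cc" else MASK_SITE[name]
        masks[r:r + side, c:c + side] = label
        boxes[name] = (r, c, side)
    return masks, boxes


def _od_to_gray(od: np.ndarray | float) -> np.ndarray | float:
    return 255.0 * 10.0 ** (-np.asarray(od, dtype=float))


def generate_bdnf_images(animal: AnimalRecord,
                         config: GeneratorConfig) -> list[SectionImage]:
    """Densitometry frames for one IHC-arm animal.

    Each section's gray values encode the configured true site OD plus a
    shared random section background OD (present in the corpus-callosum ROI
    too, so background correction removes it).  Ventral sites are darker
    than their dorsal counterparts by ``bdnf_rod_ventral_excess``.  Ground
    truth (per-site corrected OD and section background OD) rides in
    ``truth``.
    """
    if animal.arm != "IHC":
        raise ValueError(f"animal {animal.animal_id} is not in the IHC arm")
    rng = rng_for(config.seed, "bdnf", animal.animal_id)
    shape = (128, 128)
    masks, _ = _bdnf_masks(shape)
    lo, hi = config.bdnf_background_od_range
    frames = []
    for region in ("dorsal", "ventral"):
        excess = (config.bdnf_rod_ventral_excess
                  if region == "ventral" else 0.0)
        site_od = {s: config.bdnf_site_od_dorsal[s] + excess
                   for s in BDNF_SITES}
        for section in range(config.bdnf_sections_per_region):
            bg_od = float(rng.uniform(lo, hi))
            od_img = np.full(shape, bg_od + 0.02)  # plain tissue
            od_img[masks == MASK_CORPUS_CALLOSUM] = bg_od
            for site in BDNF_SITES:
                od_img[masks == MASK_SITE[site]] = site_od[site] + bg_od
            gray = _od_to_gray(od_img)
            if np.any(gray < 1.0):
                warnings.warn("true OD too dark for 8-bit encoding; gray "
                              "values clipped to 1", stacklevel=2)
                gray = np.maximum(gray, 1.0)
            gray = gray + rng.normal(0.0, config.bdnf_pixel_gray_sd, shape)
            pixels = np.clip(np.floor(gray + 0.5), 0, 255).astype(np.uint8)
            frames.append(SectionImage(
                pixels=pixels, masks=masks.copy(),
                pixel_size_um=config.pixel_size_um_bdnf, region=region,
                animal_id=animal.animal_id, section_index=section,
                truth={"site_od": dict(site_od), "background_od": bg_od}))
    return frames
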