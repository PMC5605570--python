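"""BDNF relative optical density (ROD) in the dentate gyrus.

BDNF staining is diffuse rather than punctate, so instead of a positive-area
fraction the darkness of the stain is quantified: per-pixel uncalibrated
optical density

    OD(gray) = log10(255 / max(gray, 1))

is averaged over four manually outlined rectangular sampling sites per
section (suprapyramidal blade, infrapyramidal blade, hilus, mossy fibers).
The mean OD of the corpus callosum — a fiber tract with no BDNF signal — is
measured on each section and subtracted, removing section-wide background
and illumination differences.  Per-animal, per-region, per-site values are
the average of the corrected values over that animal's sections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from dgquant.config import BDNF_SITES, MASK_CORPUS_CALLOSUM, MASK_SITE
from dgquant.core import SectionImage

__all__ = ["RodMeasure", "pixel_od", "roi_rod", "background_correct",
           "quantify_bdnf", "MissingSiteError"]

_OD_LUT = np.log10(255.0 / np.maximum(np.arange(256), 1))


@dataclass
class RodMeasure:
    animal_id: str
    region: str
    site: str
    rod_raw: float
    rod_background: float
    rod_corrected: float


class MissingSiteError(KeyError):
    """A requested sampling-site ROI is absent from the mask."""


def pixel_od(gray) -> np.ndarray | float:
    """Uncalibrated optical density of 8-bit gray values.

    Gray 0 is clamped to 1 before taking the log, capping the OD at
    log10(255) ~ 2.407; monotone decreasing in gray.
    """
    arr = np.asarray(gray)
    if np.any((arr < 0) | (arr > 255)):
        raise ValueError("gray values must lie in [0, 255]")
    od = _OD_LUT[arr.astype(np.intp)]
    return float(od) if np.isscalar(gray) else od


def roi_rod(image: SectionImage, site_label: int) -> float:
    """Mean per-pixel OD over one labelled ROI of a frame."""
    sel = np.asarray(image.masks) == site_label
    if not sel.any():
        raise MissingSiteError(
            f"no pixels carry mask label {site_label} "
            f"(animal {image.animal_id}, section {image.section_index})")
    return float(pixel_od(np.asarray(image.pixels)[sel]).mean())


def quantify_bdnf(frames: Iterable[SectionImage]) -> pd.DataFrame:
    """Raw site and corpus-callosum ROD for every frame.

    Returns a section-level tidy table (``animal_id, region, section_index,
    site, rod_raw, rod_background``); sites missing from a frame's mask are
    recorded as absent (NaN raw ROD).
    """
    rows = []
    for img in frames:
        cc = roi_rod(img, MASK_CORPUS_CALLOSUM)
        for site in BDNF_SITES:
            try:
                raw = roi_rod(img, MASK_SITE[site])
            except MissingSiteError:
                raw = np.nan
            rows.append({"animal_id": img.animal_id, "region": img.region,
                         "section_index": img.section_index, "site": site,
                         "rod_raw": raw, "rod_background": cc})
    return pd.DataFrame(rows)


def background_correct(section_table: pd.DataFrame) -> list[RodMeasure]:
    """Subtract per-section corpus-callosum ROD, then average over sections.

    Correction happens before averaging so each section's own background is
    removed.  Negative corrected values are retained (they flag sites paler
    than the fiber-tract background).
    """
    tbl = section_table.copy()
    tbl["rod_corrected"] = tbl["rod_raw"] - tbl["rod_background"]
    out = []
    for (animal, region, site), grp in sorted(
            tbl.groupby(["animal_id", "region", "site"], sort=False)):
        grp = grp.dropna(subset=["rod_raw"])
        if grp.empty:
            continue
        out.append(RodMeasure(
            animal, region, site,
            float(grp["rod_raw"].mean()),
            float(grp["rod_background"].mean()),
            float(grp["rod_corrected"].mean())))
    return out
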