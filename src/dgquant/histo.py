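"""DCX-positive area fraction of the granule cell layer.

DAB-stained new neurons appear darker than surrounding tissue, so a pixel is
counted as DCX-positive when its gray value falls strictly below a
per-section adaptive threshold

    threshold = mean - 2 * SD

computed over a stain-free reference region ("clean ROI") outlined inside
the GCL of that section.  Positive and total GCL areas are summed over
frames, sections and hemispheres per animal and region, and the normalized
score is the ratio of those pooled totals:

    DCX_normalized = sum(DCX area) / sum(GCL area)

which weights sections by the amount of GCL they contain, rather than
averaging per-section ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from dgquant.core import SectionImage

__all__ = ["ThresholdResult", "DcxQuant", "to_grayscale", "compute_threshold",
           "measure_dcx_area", "aggregate_dcx", "quantify_animal"]


@dataclass
class ThresholdResult:
    """Clean-ROI gray statistics and the derived section threshold."""

    mean_gray: float
    sd_gray: float
    threshold: float


@dataclass
class DcxQuant:
    """Per-animal, per-region pooled DCX quantification."""

    animal_id: str
    region: str
    dcx_area_um2: float
    gcl_area_um2: float
    normalized: float


class InsufficientRoiError(ValueError):
    """The clean ROI holds fewer than two pixels; no SD can be computed."""


class UndefinedRatioError(ZeroDivisionError):
    """Denominator area or quantity is zero."""


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Convert an RGB image to 8-bit gray by the Rec. 601 luminance weights.

    gray = round(0.299 R + 0.587 G + 0.114 B), rounding half up, clipped to
    [0, 255] — the conversion used by common image-analysis tools when
    flattening brightfield captures before thresholding.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {rgb.shape}")
    lum = rgb @ np.array([0.299, 0.587, 0.114])
    return np.clip(np.floor(lum + 0.5), 0, 255).astype(np.uint8)


def compute_threshold(image: SectionImage, sd_multiplier: float = 2.0,
                      ddof: int = 1) -> ThresholdResult:
    """Adaptive threshold from the stain-free clean ROI of a section.

    The SD is the sample standard deviation (``ddof=1``) by default, matching
    the histogram statistics of common image tools; ``ddof=0`` gives the
    population convention.
    """
    vals = np.asarray(image.pixels, dtype=float)[image.clean_mask]
    if vals.size < 2:
        raise InsufficientRoiError(
            f"clean ROI has {vals.size} pixel(s); need at least 2")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=ddof))
    return ThresholdResult(mean, sd, mean - sd_multiplier * sd)


def measure_dcx_area(image: SectionImage,
                     threshold: float) -> tuple[float, float]:
    """(DCX-positive area, total GCL area) of one frame, in um^2.

    Positive pixels are GCL pixels with gray value strictly below
    ``threshold``; areas are pixel counts scaled by the squared pixel size.
    """
    gcl = image.gcl_mask
    if not gcl.any():
        raise ValueError("GCL mask is empty")
    if threshold <= 0:
        warnings.warn(f"threshold {threshold:.2f} <= 0: no pixel can be "
                      "positive", stacklevel=2)
    px2 = image.pixel_size_um ** 2
    positive = int((np.asarray(image.pixels)[gcl] < threshold).sum())
    return positive * px2, int(gcl.sum()) * px2


def quantify_animal(frames: Iterable[SectionImage], *,
                    sd_multiplier: float = 2.0, ddof: int = 1,
                    per_frame_threshold: bool = False) -> pd.DataFrame:
    """Threshold and measure every frame of one animal.

    One threshold per (region, section) is computed from the clean ROI of the
    section's first frame and applied to all frames of that section's
    montage; ``per_frame_threshold=True`` switches to an independent
    threshold per frame.

    Returns a tidy frame-level table with columns ``animal_id, region,
    section_index, frame_index, threshold, dcx_area_um2, gcl_area_um2``.
    """
    frames = list(frames)
    rows = []
    thresholds: dict[tuple[str, int], float] = {}
    if not per_frame_threshold:
        for img in sorted(frames, key=lambda f: f.frame_index):
            key = (img.region, img.section_index)
            if key not in thresholds and img.clean_mask.sum() >= 2:
                thresholds[key] = compute_threshold(
                    img, sd_multiplier, ddof).threshold
    for img in frames:
        key = (img.region, img.section_index)
        if per_frame_threshold or key not in thresholds:
            thr = compute_threshold(img, sd_multiplier, ddof).threshold
        else:
            thr = thresholds[key]
        dcx, gcl = measure_dcx_area(img, thr)
        rows.append({"animal_id": img.animal_id, "region": img.region,
                     "section_index": img.section_index,
                     "frame_index": img.frame_index, "threshold": thr,
                     "dcx_area_um2": dcx, "gcl_area_um2": gcl})
    return pd.DataFrame(rows)


def aggregate_dcx(frame_table: pd.DataFrame,
                  regions: Sequence[str] = ("dorsal", "ventral"),
                  ) -> list[DcxQuant]:
    """Pool frame measurements to one normalized value per animal and region.

    DCX and GCL areas are summed over frames, sections and hemispheres
    before dividing, so the result is the pooled ratio, not a mean of
    per-section ratios.  Intermediate-region frames are excluded by the
    default ``regions`` selection, mirroring the dorsal/ventral contrast the
    quantification is designed for.
    """
    out = []
    table = frame_table[frame_table["region"].isin(regions)]
    for (animal, region), grp in sorted(
            table.groupby(["animal_id", "region"], sort=False)):
        dcx = float(grp["dcx_area_um2"].sum())
        gcl = float(grp["gcl_area_um2"].sum())
        if gcl == 0:
            raise UndefinedRatioError(
                f"animal {animal} region {region}: total GCL area is zero")
        out.append(DcxQuant(animal, region, dcx, gcl, dcx / gcl))
    return out
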