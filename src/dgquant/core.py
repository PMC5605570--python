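"""Shared domain containers passed between generator and quantifiers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dgquant.config import MASK_CLEAN_ROI, MASK_GCL


@dataclass
class SectionImage:
    """One 8-bit grayscale frame of a coronal section with its masks.

    ``masks`` is a same-shape integer label image: 0 background, 1 granule
    cell layer (GCL), 2 stain-free clean ROI (a subset of the GCL), 10-13
    the four BDNF sampling sites, 20 corpus callosum.  ``truth`` carries
    generator ground truth (empty for real data).
    """

    pixels: np.ndarray
    masks: np.ndarray
    pixel_size_um: float
    region: str
    animal_id: str = ""
    hemisphere: str = "pooled"
    section_index: int = 0
    frame_index: int = 0
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.masks = np.asarray(self.masks)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D gray-value array")
        if self.masks.shape != self.pixels.shape:
            raise ValueError(
                f"mask shape {self.masks.shape} does not match pixel grid "
                f"{self.pixels.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def gcl_mask(self) -> np.ndarray:
        """GCL pixels; the clean ROI is part of the GCL."""
        return (self.masks == MASK_GCL) | (self.masks == MASK_CLEAN_ROI)

    @property
    def clean_mask(self) -> np.ndarray:
        return self.masks == MASK_CLEAN_ROI


@dataclass
class AnimalRecord:
    """One mouse: housing, treatment arm, and video identification mark."""

    animal_id: str
    batch: int
    cage_id: str
    treatment: str        # "E" enriched / "C" control
    arm: str              # "IHC" / "PCR" / "ELISA"
    mark_pattern: str     # "none" / "one_stripe" / "two_stripes" (E only)
    staining_method: str = ""  # "cresyl" / "antibody", IHC arm only


@dataclass
class SectionOutline:
    """Area of one outlined subfield on one serial section."""

    animal_id: str
    region: str            # dorsal / intermediate / ventral
    subfield: str          # DG / CA
    section_position_um: float
    area_um2: float
    spacing_to_next_um: float
    staining_method: str = "cresyl"


@dataclass
class ActivityLog:
    """One cage-day of wheel running: counter total plus sampled video.

    ``windows`` maps each sampled hour to per-mouse observed running seconds
    within the first 3 minutes of that hour, ordered as ``mouse_ids``.
    """

    cage_id: str
    day: int
    mouse_ids: list[str]
    total_spins: float
    windows: list[tuple[int, np.ndarray]]
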