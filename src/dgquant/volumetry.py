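"""Cavalieri volume estimation from serial-section outlines.

The hippocampus is outlined on serial coronal sections — dorsal fields every
480 um, intermediate and ventral fields every 240 um — and each region x
subfield (DG, CA) volume is the Cavalieri sum

    V = sum_i A_i * s_i

where ``s_i`` is the distance to the next section and the last section
contributes ``A_last * 240 um`` regardless of the sampling interval
(``last_section_rule="fixed"``, the rule as stated in the emulated
outlining protocol; pass ``"interval"`` to use the stack's own spacing for
the last section instead).
Volumes are reported in mm^3; hemispheres are pooled upstream, so outlines
carry no hemisphere field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from dgquant.core import SectionOutline

__all__ = ["VolumeEstimate", "cavalieri_volume", "estimate_volumes",
           "dgca_ratio"]

LAST_SECTION_UM = 240.0


@dataclass
class VolumeEstimate:
    animal_id: str
    region: str
    subfield: str
    volume_mm3: float
    staining_method: str = ""


def cavalieri_volume(outlines: Sequence[SectionOutline],
                     last_section_rule: str = "fixed") -> VolumeEstimate:
    """Volume of one animal/region/subfield stack of outlines."""
    if not outlines:
        raise ValueError("no outlines supplied")
    keys = {(o.animal_id, o.region, o.subfield) for o in outlines}
    if len(keys) > 1:
        raise ValueError(f"outlines mix several stacks: {sorted(keys)}")
    positions = [o.section_position_um for o in outlines]
    if len(set(positions)) < len(positions):
        raise ValueError("duplicate section positions in outline stack")
    ordered = sorted(outlines, key=lambda o: o.section_position_um)
    if [o.section_position_um for o in ordered] != positions:
        warnings.warn("outlines were not ordered by position; reordered",
                      stacklevel=2)
    if last_section_rule == "fixed":
        last = LAST_SECTION_UM
    elif last_section_rule == "interval":
        last = ordered[-1].spacing_to_next_um
    else:
        raise ValueError("last_section_rule must be 'fixed' or 'interval'")
    vol_um3 = sum(o.area_um2 * o.spacing_to_next_um for o in ordered[:-1])
    vol_um3 += ordered[-1].area_um2 * last
    animal, region, subfield = next(iter(keys))
    return VolumeEstimate(animal, region, subfield, vol_um3 / 1e9,
                          ordered[0].staining_method)


def estimate_volumes(outlines: Iterable[SectionOutline],
                     last_section_rule: str = "fixed") -> pd.DataFrame:
    """Cavalieri volume for every animal/region/subfield stack.

    Returns a tidy table (``animal_id, region, subfield, staining_method,
    volume_mm3``).
    """
    stacks: dict[tuple, list[SectionOutline]] = {}
    for o in outlines:
        stacks.setdefault((o.animal_id, o.region, o.subfield), []).append(o)
    rows = []
    for key in sorted(stacks):
        est = cavalieri_volume(stacks[key], last_section_rule)
        rows.append({"animal_id": est.animal_id, "region": est.region,
                     "subfield": est.subfield,
                     "staining_method": est.staining_method,
                     "volume_mm3": est.volume_mm3})
    return pd.DataFrame(rows)


def dgca_ratio(volumes: pd.DataFrame) -> pd.DataFrame:
    """DG/CA volume ratio per animal and region, with cohort means.

    Returns a table with per-animal rows (``animal_id, region, ratio``) and,
    under animal_id ``"cohort_mean"``, the mean ratio per region.
    """
    wide = volumes.pivot_table(index=["animal_id", "region"],
                               columns="subfield", values="volume_mm3")
    if "DG" not in wide or "CA" not in wide:
        raise ValueError("both DG and CA volumes are required")
    if (wide["CA"] == 0).any():
        bad = wide.index[wide["CA"] == 0].tolist()
        raise ZeroDivisionError(f"CA volume is zero for {bad}")
    out = wide.reset_index()
    out["ratio"] = out["DG"] / out["CA"]
    out = out[["animal_id", "region", "ratio"]]
    means = (out.groupby("region", sort=True)["ratio"].mean().reset_index())
    means.insert(0, "animal_id", "cohort_mean")
    return pd.concat([out, means], ignore_index=True)
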