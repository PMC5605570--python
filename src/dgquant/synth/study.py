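"""Whole-study generation and on-disk layout.

``generate_study`` draws every modality for one seeded config and keeps it
in memory; ``write_study`` lays a study out on disk in the documented
exchange formats (8-bit grayscale TIFF images with same-shape label-image
masks, CSV tables, a YAML config snapshot), which is also what the CLI
quantifiers consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from dgquant.config import GeneratorConfig
from dgquant.core import AnimalRecord, SectionImage, SectionOutline
from dgquant.synth.behavior import (ActivityExpression,
                                    generate_activity_and_expression)
from dgquant.synth.cohort import generate_cohort
from dgquant.synth.images import generate_bdnf_images, generate_section_images
from dgquant.synth.outlines import generate_outlines

__all__ = ["SyntheticStudy", "generate_study", "write_study"]


@dataclass
class SyntheticStudy:
    config: GeneratorConfig
    cohort: list[AnimalRecord]
    dcx_frames: list[SectionImage] = field(default_factory=list)
    bdnf_frames: list[SectionImage] = field(default_factory=list)
    outlines: list[SectionOutline] = field(default_factory=list)
    volume_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    behavior: ActivityExpression | None = None

    @property
    def animals(self) -> pd.DataFrame:
        return pd.DataFrame([vars(a) for a in self.cohort])

    def dcx_truth(self) -> pd.DataFrame:
        """Per-frame true stained fractions of the DCX images."""
        rows = [{"animal_id": f.animal_id, "region": f.region,
                 "section_index": f.section_index, **f.truth}
                for f in self.dcx_frames]
        return pd.DataFrame(rows)


def generate_study(config: GeneratorConfig, *, images: bool = True,
                   bdnf_images: bool = True, outlines: bool = True,
                   behavior: bool = True) -> SyntheticStudy:
    """Generate all requested modalities for one seeded config.

    Flags allow skipping expensive modalities when only part of the study is
    needed; determinism is per modality and per animal, so a partial study
    is identical to the corresponding slice of a full one.
    """
    config.validate()
    cohort = generate_cohort(config)
    study = SyntheticStudy(config=config, cohort=cohort)
    ihc = [a for a in cohort if a.arm == "IHC"]
    if images:
        for animal in ihc:
            study.dcx_frames.extend(generate_section_images(animal, config))
    if bdnf_images:
        for animal in ihc:
            study.bdnf_frames.extend(generate_bdnf_images(animal, config))
    if outlines:
        truth_rows = []
        for animal in ihc:
            outl, truth = generate_outlines(animal, config)
            study.outlines.extend(outl)
            truth_rows += [
                {"animal_id": animal.animal_id, "region": region,
                 "subfield": subfield, "volume_mm3": vol}
                for (region, subfield), vol in truth.items()]
        study.volume_truth = pd.DataFrame(truth_rows)
    if behavior:
        study.behavior = generate_activity_and_expression(cohort, config)
    return study


def _activity_table(behavior: ActivityExpression) -> pd.DataFrame:
    rows = []
    for log in behavior.logs:
        for hour, seconds in log.windows:
            for mouse, s in zip(log.mouse_ids, seconds):
                rows.append({"cage_id": log.cage_id, "day": log.day,
                             "total_spins": log.total_spins, "hour": hour,
                             "animal_id": mouse,
                             "observed_seconds": float(s)})
    return pd.DataFrame(rows)


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write a study to ``outdir``; returns the paths written.

    Images land under ``images/`` as ``<animal>_<stain>_<region>_s<k>.tif``
    with a matching ``_mask.tif`` label image; tables are CSV; the config
    snapshot is ``config.yaml``; ground truth goes to ``truth_*.csv``.
    """
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _csv(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        paths[name] = path

    study.config.to_yaml(outdir / "config.yaml")
    paths["config.yaml"] = outdir / "config.yaml"
    _csv("animals.csv", study.animals)
    for stain, frames in (("dcx", study.dcx_frames),
                          ("bdnf", study.bdnf_frames)):
        for f in frames:
            stem = (f"{f.animal_id}_{stain}_{f.region}_s{f.section_index}")
            tifffile.imwrite(outdir / "images" / f"{stem}.tif",
                             f.pixels.astype(np.uint8))
            tifffile.imwrite(outdir / "images" / f"{stem}_mask.tif",
                             f.masks.astype(np.uint8))
    if study.dcx_frames:
        _csv("truth_dcx.csv", study.dcx_truth())
    if study.outlines:
        _csv("outlines.csv", pd.DataFrame([vars(o) for o in study.outlines]))
        _csv("truth_volumes.csv", study.volume_truth)
    if study.behavior is not None:
        _csv("activity.csv", _activity_table(study.behavior))
        _csv("expression.csv", study.behavior.expression)
        _csv("standards.csv", study.behavior.standards)
        _csv("truth_distance.csv", study.behavior.truth_distance)
        _csv("truth_expression.csv", study.behavior.truth_expression)
    return paths
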