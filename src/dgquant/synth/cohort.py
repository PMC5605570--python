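"""Cohort design: batches, cages, treatments, assay arms, video marks.

The reference design runs 4 batches of 24 mice housed 3 per cage; within a
batch, half the cages are assigned to the enriched condition (E) and half to
control (C).  Each cage contributes exactly one mouse to each assay arm —
immunohistochemistry (IHC), RT-PCR, and ELISA — so with defaults every arm
holds 16 mice per treatment, one per cage.  Enriched mice carry one of three
hair-dye mark patterns for video identification.  IHC-arm brains are split
roughly half and half between cresyl-violet and antibody counterstaining for
the volumetric outlines.
"""

from __future__ import annotations

from dgquant.config import ARMS, GeneratorConfig
from dgquant.core import AnimalRecord
from dgquant.synth.seeding import rng_for

MARKS = ("none", "one_stripe", "two_stripes")


def generate_cohort(config: GeneratorConfig) -> list[AnimalRecord]:
    """Deterministic cohort of :class:`AnimalRecord` for the configured design."""
    config.validate()
    if config.mice_per_cage != len(ARMS):
        raise ValueError(
            f"arm-per-cage design needs {len(ARMS)} mice per cage")
    rng = rng_for(config.seed, "cohort")
    records: list[AnimalRecord] = []
    for batch in range(1, config.n_batches + 1):
        cages = config.cages_per_batch
        treatments = ["E"] * (cages // 2) + ["C"] * (cages // 2)
        rng.shuffle(treatments)
        for cage_idx, treatment in enumerate(treatments, start=1):
            cage_id = f"B{batch}C{cage_idx}"
            arms = list(ARMS)
            rng.shuffle(arms)
            marks = list(MARKS)
            rng.shuffle(marks)
            for mouse_idx, arm in enumerate(arms, start=1):
                records.append(AnimalRecord(
                    animal_id=f"{cage_id}M{mouse_idx}",
                    batch=batch,
                    cage_id=cage_id,
                    treatment=treatment,
                    arm=arm,
                    mark_pattern=(marks[mouse_idx - 1]
                                  if treatment == "E" else "none")))
    # counterstain assignment for the volumetry slides: split the IHC arm
    # as evenly as possible between the two staining methods
    ihc = [r for r in records if r.arm == "IHC"]
    order = rng.permutation(len(ihc))
    for rank, idx in enumerate(order):
        ihc[idx].staining_method = "cresyl" if rank < len(ihc) // 2 \
            else "antibody"
    return records
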