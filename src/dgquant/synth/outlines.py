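"""Synthetic serial-section outline areas with exact Cavalieri ground truth.

Per animal, region and subfield a target volume is drawn from the config
(control CA volumes, DG as the configured fraction of CA, dorsal volumes
scaled up by the enrichment effect for E animals, lognormal animal and
subfield variation).  A smooth random area profile is then rescaled so that
its Cavalieri sum under the estimator's own last-section rule equals the
target exactly, so volume recovery error reflects only cohort-level noise,
never the estimator.
"""

from __future__ import annotations

import numpy as np

from dgquant.config import (REGIONS, SUBFIELDS, GeneratorConfig,
                            InvalidConfigError)
from dgquant.core import AnimalRecord, SectionOutline
from dgquant.volumetry import LAST_SECTION_UM
from dgquant.synth.seeding import ln_noise, rng_for

__all__ = ["generate_outlines"]


def generate_outlines(animal: AnimalRecord, config: GeneratorConfig,
                      ) -> tuple[list[SectionOutline], dict]:
    """(outlines, truth) for one animal.

    ``truth`` maps ``(region, subfield)`` to the true volume in mm^3.
    Dorsal stacks are sampled every 480 um, intermediate and ventral stacks
    every 240 um, mirroring the outlining protocol.
    """
    rng = rng_for(config.seed, "volume", animal.animal_id)
    animal_scale = ln_noise(rng, config.volume_animal_sigma)
    outlines: list[SectionOutline] = []
    truth: dict[tuple[str, str], float] = {}
    for region in REGIONS:
        dorsal = region == "dorsal"
        n = config.sections_dorsal if dorsal else config.sections_other
        spacing = config.spacing_dorsal_um if dorsal \
            else config.spacing_other_um
        for subfield in SUBFIELDS:
            target = config.ca_volume_mm3[region]
            if subfield == "DG":
                target *= config.dgca_ratio[region]
            if dorsal and animal.treatment == "E":
                target *= 1.0 + config.volume_effect_dorsal
            target *= animal_scale * ln_noise(
                rng, config.volume_subfield_sigma)
            if target <= 0:
                raise InvalidConfigError(
                    f"non-positive target volume for {region}/{subfield}")
            # smooth bump profile with mild section-to-section noise
            i = np.arange(n)
            profile = (np.sin(np.pi * (i + 0.5) / n) + 0.3)
            profile *= rng.lognormal(0.0, 0.1, n)
            weights = np.full(n, spacing)
            weights[-1] = LAST_SECTION_UM  # the estimator's last-section rule
            scale = target * 1e9 / float(profile @ weights)
            areas = profile * scale
            start = float(rng.uniform(0.0, spacing))
            for j in range(n):
                outlines.append(SectionOutline(
                    animal_id=animal.animal_id, region=region,
                    subfield=subfield,
                    section_position_um=start + j * spacing,
                    area_um2=float(areas[j]),
                    spacing_to_next_um=spacing,
                    staining_method=animal.staining_method or "cresyl"))
            truth[(region, subfield)] = target
    return outlines, truth
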