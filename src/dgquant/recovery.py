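"""Parameter-recovery benchmarks on synthetic cohorts.

Each function generates cohorts at the reference design scale (16 animals
per treatment in the relevant arm), runs the corresponding quantification
pipeline end to end, and summarizes how well the configured effect sizes
are recovered, averaging over independently seeded replicate studies to
suppress cohort-level sampling noise.  These are the quantities a user
would quote when validating the pipeline.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from dgquant import pipeline, volumetry
from dgquant import stats as dgstats
from dgquant.config import GeneratorConfig
from dgquant.synth import generate_study

__all__ = ["derive_seeds", "dcx_fold_recovery", "protein_fold_recovery",
           "volume_recovery", "bdnf_distance_r2_recovery",
           "design_constants", "interaction_rejection_rate"]


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """``n`` distinct study seeds derived reproducibly from one base seed."""
    ss = np.random.SeedSequence(int(base_seed) & 0x7FFFFFFF)
    return [int(s) for s in
            ss.generate_state(n, dtype=np.uint32) % (2 ** 31 - 1)]


def _mean_by_cell(df, value):
    return df.groupby(["region", "treatment"])[value].mean()


def dcx_fold_recovery(seeds: Sequence[int]) -> dict[str, float]:
    """Image-pipeline DCX fold change, averaged over replicate cohorts.

    Returns the mean enriched/control ratio of cohort-mean normalized DCX
    in dorsal DG and the control/enriched ratio in ventral DG.
    """
    dorsal, ventral = [], []
    for seed in seeds:
        study = generate_study(GeneratorConfig(seed=seed),
                               bdnf_images=False, outlines=False,
                               behavior=False)
        cells = _mean_by_cell(pipeline.dcx_table(study), "normalized")
        dorsal.append(cells["dorsal", "E"] / cells["dorsal", "C"])
        ventral.append(cells["ventral", "C"] / cells["ventral", "E"])
    return {"dorsal_fold_ec": float(np.mean(dorsal)),
            "ventral_fold_ce": float(np.mean(ventral))}


def protein_fold_recovery(seeds: Sequence[int]) -> dict[str, float]:
    """ELISA-arm DCX/PROX1 fold change recovered per region."""
    dorsal, ventral = [], []
    for seed in seeds:
        study = generate_study(GeneratorConfig(seed=seed), images=False,
                               bdnf_images=False, outlines=False)
        cells = _mean_by_cell(pipeline.protein_table(study),
                              "normalized_dcx")
        dorsal.append(cells["dorsal", "E"] / cells["dorsal", "C"])
        ventral.append(cells["ventral", "C"] / cells["ventral", "E"])
    return {"dorsal_fold_ec": float(np.mean(dorsal)),
            "ventral_fold_ce": float(np.mean(ventral))}


def volume_recovery(seeds: Sequence[int]) -> dict[str, float]:
    """Cavalieri volume effects: dorsal enrichment excess and DG/CA ratios.

    ``dorsal_excess_pct`` is 100*(mean_E/mean_C - 1) of dorsal DG+CA
    volume; ``*_dgca_pct`` are cohort-mean DG/CA percentages per region.
    """
    excess, ratios = [], {"dorsal": [], "intermediate": [], "ventral": []}
    for seed in seeds:
        study = generate_study(GeneratorConfig(seed=seed), images=False,
                               bdnf_images=False, behavior=False)
        vols = pipeline.volume_table(study)
        dorsal = (vols[vols.region == "dorsal"]
                  .groupby(["animal_id", "treatment"], as_index=False)
                  ["volume_mm3"].sum())
        mean_e = dorsal[dorsal.treatment == "E"]["volume_mm3"].mean()
        mean_c = dorsal[dorsal.treatment == "C"]["volume_mm3"].mean()
        excess.append(100.0 * (mean_e / mean_c - 1.0))
        table = volumetry.dgca_ratio(vols)
        cohort = table[table.animal_id == "cohort_mean"]
        for region in ratios:
            ratios[region].append(
                float(cohort[cohort.region == region]["ratio"].iloc[0]))
    return {"dorsal_excess_pct": float(np.mean(excess)),
            "ventral_dgca_pct": float(100 * np.mean(ratios["ventral"])),
            "intermediate_dgca_pct":
                float(100 * np.mean(ratios["intermediate"])),
            "dorsal_dgca_pct": float(100 * np.mean(ratios["dorsal"]))}


def bdnf_distance_r2_recovery(seeds: Sequence[int]) -> dict[str, float]:
    """Ventral/dorsal r^2 of Bdnf/Prox1 vs estimated running distance.

    Distances come from the spin-allocation estimator, expression from the
    standard-curve qPCR pipeline; enriched PCR-arm animals only.
    """
    ventral, dorsal = [], []
    for seed in seeds:
        study = generate_study(GeneratorConfig(seed=seed), images=False,
                               bdnf_images=False, outlines=False)
        mrna = pipeline.mrna_table(study)
        dists = pipeline.distance_table(study)
        e = mrna[mrna.treatment == "E"].merge(dists, on="animal_id")
        r2 = dgstats.covariate_r2(e, "normalized_bdnf", "distance_km",
                                  by="region")
        ventral.append(r2["ventral"])
        dorsal.append(r2["dorsal"])
    return {"ventral_r2": float(np.mean(ventral)),
            "dorsal_r2": float(np.mean(dorsal))}


def design_constants(seed: int = 0) -> dict[str, int]:
    """Cohort sizes of the default design."""
    from dgquant.synth import generate_cohort

    cohort = generate_cohort(GeneratorConfig(seed=seed))
    return {
        "n_animals": len(cohort),
        "n_ihc_enriched": sum(1 for a in cohort
                              if a.arm == "IHC" and a.treatment == "E"),
        "n_ihc_control": sum(1 for a in cohort
                             if a.arm == "IHC" and a.treatment == "C"),
    }


def interaction_rejection_rate(seeds: Sequence[int],
                               null: bool = False) -> float:
    """Fraction of replicate cohorts rejecting treatment x region at 0.05.

    Fits the exchangeable GEE to the Dcx/Prox1 mRNA table of each study
    and reads the Wald p of the interaction; with ``null=True`` every
    treatment effect is switched off, so this measures type-I error.
    """
    hits = 0
    for seed in seeds:
        cfg = GeneratorConfig(seed=seed)
        if null:
            cfg = cfg.null()
        study = generate_study(cfg, images=False, bdnf_images=False,
                               outlines=False)
        mrna = pipeline.mrna_table(study)
        fit = dgstats.gee_fit(mrna, "normalized_dcx ~ treatment * region",
                              groups="animal_id")
        inter = fit.wald_table[fit.wald_table.effect.str.contains(":")]
        hits += float(inter["p"].iloc[0]) < 0.05
    return hits / len(seeds)
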