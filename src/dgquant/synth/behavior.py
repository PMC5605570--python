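"""Synthetic wheel-running logs and molecular expression tables.

Wheel running: every enriched cage has three mice sharing three counted
wheels.  Per-mouse daily spins are drawn from lognormal running propensities
with day-to-day variation; the cage counter records the (rounded) daily
total, and each sampled 3-minute video window records per-mouse running
seconds proportional to that day's true activity shares with multiplicative
observation noise.  Control cages have no wheels and produce no logs.

Expression: PCR-arm animals yield Cq tables for Dcx, Bdnf and Prox1 plus a
serial-dilution standards table per gene (efficiencies drawn from the
configured 98-104% range); ELISA-arm animals yield DCX and PROX1 protein
quantities.  True Dcx/Prox1 ratios follow the configured region x treatment
folds.  Ventral Bdnf/Prox1 of enriched animals is linear in the true
distance run with the configured squared correlation; the residual SD is
budgeted so the target r^2 holds at the *measured* level, i.e. after Cq
noise has been added and inverted through the standard curve.  Dorsal Bdnf
is independent of running.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dgquant.config import DCX_REGIONS, GeneratorConfig
from dgquant.core import ActivityLog, AnimalRecord
from dgquant.synth.seeding import ln_noise, rng_for

__all__ = ["ActivityExpression", "generate_cage_activity",
           "generate_activity_and_expression"]

GENES_MRNA = ("Dcx", "Bdnf", "Prox1")


@dataclass
class ActivityExpression:
    """Activity logs, molecular tables, and their ground truth."""

    logs: list[ActivityLog]
    expression: pd.DataFrame   # animal_id, region, modality, gene, measure, value
    standards: pd.DataFrame    # gene, quantity, cq
    truth_distance: pd.DataFrame   # animal_id, distance_km (E mice only)
    truth_expression: pd.DataFrame  # animal_id, region, modality, gene, ratio


def generate_cage_activity(rng: np.random.Generator, config: GeneratorConfig,
                           mouse_ids: list[str],
                           propensities: np.ndarray | None = None,
                           cage_id: str | None = None,
                           ) -> tuple[list[ActivityLog], np.ndarray]:
    """Logs for one enriched cage plus each mouse's true total spins.

    ``propensities`` (mean daily spins per mouse) defaults to lognormal
    draws; a propensity of zero produces zero observed seconds in every
    window for that mouse.
    """
    n = len(mouse_ids)
    if cage_id is None:
        cage_id = mouse_ids[0].rsplit("M", 1)[0]
    if propensities is None:
        propensities = rng.lognormal(np.log(config.propensity_mean_spins),
                                     config.propensity_sigma, n)
    propensities = np.asarray(propensities, dtype=float)
    logs = []
    true_spins = np.zeros(n)
    for day in range(1, config.days + 1):
        daily = propensities * rng.lognormal(0.0, config.daily_sigma, n)
        true_spins += daily
        total = daily.sum()
        shares = daily / total if total > 0 else np.zeros(n)
        windows = []
        for hour in range(config.windows_per_day):
            level = rng.uniform(0.05, 0.45)
            frac = (n * shares * level
                    * rng.lognormal(0.0, config.observation_sigma, n))
            seconds = config.window_seconds * np.clip(frac, 0.0, 1.0)
            windows.append((hour, seconds))
        logs.append(ActivityLog(cage_id=cage_id,
                                day=day, mouse_ids=list(mouse_ids),
                                total_spins=float(np.round(total)),
                                windows=windows))
    return logs, true_spins


def _measured_ratio_sd(config: GeneratorConfig, mean_ratio: float) -> float:
    """SD added to a quantity ratio by Cq noise on the two genes.

    A Cq error of sd ``s`` maps to a log10-quantity error of ``s/|b|``; the
    nominal slope of a perfectly efficient curve is ``-1/log10(2)``.
    """
    slope = 1.0 / np.log10(2.0)
    log10_sd = config.cq_sd / slope
    ln_sd = np.sqrt(2.0) * log10_sd * np.log(10.0)
    return float(mean_ratio * ln_sd)


def generate_activity_and_expression(cohort: list[AnimalRecord],
                                     config: GeneratorConfig,
                                     ) -> ActivityExpression:
    """Activity logs for enriched cages and molecular tables for all animals.

    Molecular samples are produced for the PCR and ELISA arms (the IHC arm
    is consumed whole by histology).  All randomness derives from the study
    seed, cage ids and animal ids, so the output is order independent.
    """
    rng_cfg = rng_for(config.seed, "curves")
    # wheel running: enriched cages only
    logs: list[ActivityLog] = []
    true_distance: dict[str, float] = {}
    cages: dict[str, list[AnimalRecord]] = {}
    for rec in cohort:
        cages.setdefault(rec.cage_id, []).append(rec)
    for cage_id in sorted(cages):
        members = sorted(cages[cage_id], key=lambda r: r.animal_id)
        if members[0].treatment != "E":
            continue
        rng = rng_for(config.seed, "activity", cage_id)
        cage_logs, spins = generate_cage_activity(
            rng, config, [m.animal_id for m in members], cage_id=cage_id)
        logs.extend(cage_logs)
        for m, s in zip(members, spins):
            true_distance[m.animal_id] = (
                s * config.wheel_circumference_m / 1000.0)

    # qPCR standard curves, one per gene
    lo, hi = config.efficiency_range
    curves = {}
    standards_rows = []
    for gene in GENES_MRNA:
        eff = float(rng_cfg.uniform(lo, hi))
        slope = -1.0 / np.log10(1.0 + eff)
        intercept = float(rng_cfg.uniform(21.0, 25.0))
        curves[gene] = (intercept, slope)
        for dec in range(config.standards_decades):
            q = 10.0 ** (2 - dec)
            cq = (intercept + slope * np.log10(q)
                  + rng_cfg.normal(0.0, config.cq_sd_standards))
            standards_rows.append({"gene": gene, "quantity": q,
                                   "cq": float(cq)})

    # true expression ratios per animal x region
    expr_rows = []
    truth_rows = []
    pcr_e = sorted(a.animal_id for a in cohort
                   if a.arm == "PCR" and a.treatment == "E")
    dist = np.array([true_distance[a] for a in pcr_e])
    if dist.size >= 3 and dist.std() > 0:
        z = (dist - dist.mean()) / dist.std()
    else:
        z = np.zeros(dist.size)
    zmap = dict(zip(pcr_e, z))
    sig = config.bdnf_distance_signal_sd
    mu_v = config.bdnf_mrna_base["ventral"]
    meas_var = _measured_ratio_sd(config, mu_v) ** 2
    resid_var = max(
        sig ** 2 * (1.0 / config.bdnf_distance_r2_ventral - 1.0) - meas_var,
        0.0)
    resid_sd = float(np.sqrt(resid_var))

    for rec in sorted(cohort, key=lambda r: r.animal_id):
        if rec.arm == "IHC":
            continue
        rng = rng_for(config.seed, "expression", rec.animal_id)
        for region in DCX_REGIONS:
            prox1 = rng.lognormal(np.log(config.prox1_mean_qty),
                                  config.prox1_sigma)
            enriched = rec.treatment == "E"
            if rec.arm == "PCR":
                dcx_ratio = (config.dcx_mrna_base[region]
                             * (config.dcx_fold_enriched[region]
                                if enriched else 1.0)
                             * ln_noise(rng, config.ratio_sigma))
                if region == "ventral" and enriched:
                    bdnf_ratio = max(
                        mu_v + sig * zmap.get(rec.animal_id, 0.0)
                        + rng.normal(0.0, resid_sd), 0.02)
                else:
                    bdnf_ratio = (config.bdnf_mrna_base[region]
                                  * ln_noise(rng, config.ratio_sigma))
                quantities = {"Dcx": prox1 * dcx_ratio,
                              "Bdnf": prox1 * bdnf_ratio, "Prox1": prox1}
                for gene, qty in quantities.items():
                    a, b = curves[gene]
                    cq = (a + b * np.log10(qty)
                          + rng.normal(0.0, config.cq_sd))
                    expr_rows.append({
                        "animal_id": rec.animal_id, "region": region,
                        "modality": "mRNA", "gene": gene, "measure": "cq",
                        "value": float(cq)})
                truth_rows += [
                    {"animal_id": rec.animal_id, "region": region,
                     "modality": "mRNA", "gene": "Dcx", "ratio": dcx_ratio},
                    {"animal_id": rec.animal_id, "region": region,
                     "modality": "mRNA", "gene": "Bdnf", "ratio": bdnf_ratio},
                ]
            else:  # ELISA arm: DCX and PROX1 protein
                dcx_ratio = (config.dcx_protein_base[region]
                             * (config.protein_fold[region]
                                if enriched else 1.0)
                             * ln_noise(rng, config.ratio_sigma))
                for gene, qty in (("DCX", prox1 * dcx_ratio),
                                  ("PROX1", prox1)):
                    expr_rows.append({
                        "animal_id": rec.animal_id, "region": region,
                        "modality": "protein", "gene": gene,
                        "measure": "pg",
                        "value": float(qty * ln_noise(
                            rng, config.elisa_cv))})
                truth_rows.append(
                    {"animal_id": rec.animal_id, "region": region,
                     "modality": "protein", "gene": "DCX",
                     "ratio": dcx_ratio})

    dist_df = pd.DataFrame(
        [{"animal_id": a, "distance_km": d}
         for a, d in sorted(true_distance.items())])
    return ActivityExpression(
        logs=logs,
        expression=pd.DataFrame(expr_rows),
        standards=pd.DataFrame(standards_rows),
        truth_distance=dist_df,
        truth_expression=pd.DataFrame(truth_rows))
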