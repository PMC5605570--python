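"""End-to-end orchestration: generate -> quantify -> analyze -> report.

``run_full_study`` draws a complete synthetic study, runs every quantifier,
fits the repeated-measures models, and returns a report with six headline
analyses (DCX immunohistochemistry, DCX mRNA, DCX protein, BDNF
immunohistochemistry, BDNF mRNA, hippocampal volumes), each carrying a Wald
test table, pairwise comparisons, and a recovery-vs-truth table of the
enrichment folds.  The quantification adapters in this module are the same
entry points the acceptance checks use.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dgquant import __version__, activity, densitometry, histo, molecular
from dgquant import stats as dgstats
from dgquant import volumetry
from dgquant.config import GeneratorConfig
from dgquant.synth import generate_study, write_study
from dgquant.synth.study import SyntheticStudy

__all__ = ["RunManifest", "run_full_study", "validate_inputs",
           "dcx_table", "bdnf_rod_table", "volume_table", "distance_table",
           "mrna_table", "protein_table"]


# ---------------------------------------------------------------------------
# quantification adapters (synthetic study -> tidy per-animal tables)

def _with_design(df: pd.DataFrame, study: SyntheticStudy) -> pd.DataFrame:
    return df.merge(
        study.animals[["animal_id", "cage_id", "treatment", "arm",
                       "staining_method"]],
        on="animal_id", how="left")


def dcx_table(study: SyntheticStudy) -> pd.DataFrame:
    """Threshold, measure and aggregate every IHC animal's DCX frames."""
    by_animal: dict[str, list] = {}
    for f in study.dcx_frames:
        by_animal.setdefault(f.animal_id, []).append(f)
    quants = []
    for frames in by_animal.values():
        table = histo.quantify_animal(
            frames, sd_multiplier=study.config.threshold_sd_multiplier,
            ddof=study.config.threshold_sd_ddof)
        quants.extend(histo.aggregate_dcx(table))
    df = pd.DataFrame([vars(q) for q in quants])
    return _with_design(df, study)


def bdnf_rod_table(study: SyntheticStudy) -> pd.DataFrame:
    """Background-corrected ROD per animal, region and site."""
    sections = densitometry.quantify_bdnf(study.bdnf_frames)
    measures = densitometry.background_correct(sections)
    df = pd.DataFrame([vars(m) for m in measures])
    return _with_design(df, study)


def volume_table(study: SyntheticStudy) -> pd.DataFrame:
    """Cavalieri volume per animal, region and subfield."""
    df = volumetry.estimate_volumes(
        study.outlines, last_section_rule=study.config.last_section_rule)
    return _with_design(df.drop(columns="staining_method"), study)


def distance_table(study: SyntheticStudy) -> pd.DataFrame:
    """Estimated running distance per enriched mouse."""
    assert study.behavior is not None
    return activity.estimate_distances(
        study.behavior.logs, study.config.wheel_circumference_m)


def mrna_table(study: SyntheticStudy) -> pd.DataFrame:
    """Standard-curve quantification and Prox1 normalization, PCR arm."""
    assert study.behavior is not None
    expr = study.behavior.expression
    expr = expr[expr["modality"] == "mRNA"]
    curves = {}
    for gene, grp in study.behavior.standards.groupby("gene"):
        curves[gene] = molecular.fit_standard_curve(
            grp["quantity"], grp["cq"])
    qty = expr.copy()
    qty["quantity"] = [molecular.quantify(cq, curves[g])
                       for g, cq in zip(qty["gene"], qty["value"])]
    wide = qty.pivot_table(index=["animal_id", "region"], columns="gene",
                           values="quantity").reset_index()
    wide = wide.rename(columns={"Dcx": "dcx_qty", "Bdnf": "bdnf_qty",
                                "Prox1": "prox1_qty"})
    wide["modality"] = "mRNA"
    out = molecular.normalize_expression(wide)
    return _with_design(out, study)


def protein_table(study: SyntheticStudy) -> pd.DataFrame:
    """PROX1-normalized DCX protein per animal and region, ELISA arm."""
    assert study.behavior is not None
    expr = study.behavior.expression
    expr = expr[expr["modality"] == "protein"]
    wide = expr.pivot_table(index=["animal_id", "region"], columns="gene",
                            values="value").reset_index()
    wide = wide.rename(columns={"DCX": "dcx_qty", "PROX1": "prox1_qty"})
    wide["modality"] = "protein"
    out = molecular.normalize_expression(wide)
    return _with_design(out, study)


# ---------------------------------------------------------------------------
# analysis blocks

def _fold_recovery(df: pd.DataFrame, value: str,
                   truth: dict[str, float]) -> list[dict]:
    rows = []
    for region, true_fold in truth.items():
        cell = df[df["region"] == region]
        mean_e = cell.loc[cell["treatment"] == "E", value].mean()
        mean_c = cell.loc[cell["treatment"] == "C", value].mean()
        rows.append({"region": region, "estimated_fold":
                     float(mean_e / mean_c), "true_fold": float(true_fold)})
    return rows


def _analysis_block(df: pd.DataFrame, value: str, config: GeneratorConfig,
                    truth_folds: dict[str, float],
                    extra_terms: str = "") -> dict:
    """Outlier screen, GEE treatment x region fit, LSD cells, fold recovery."""
    clean, audit = dgstats.outlier_screen(
        df.dropna(subset=[value]), value, ["treatment", "region"],
        multiplier=config.iqr_multiplier)
    formula = f"{value} ~ treatment * region" + extra_terms
    fit = dgstats.gee_fit(clean, formula, groups="animal_id",
                          cov_struct=config.working_correlation)
    cells = pd.DataFrame(
        [(t, r) for t in ("E", "C")
         for r in sorted(clean["region"].unique())],
        columns=["treatment", "region"])
    for col in clean.columns:  # covariates held at reference/mean
        if col in ("treatment", "region") or col not in formula:
            continue
        cells[col] = (clean[col].iloc[0] if clean[col].dtype == object
                      else clean[col].mean())
    posthoc = dgstats.lsd_posthoc(fit, cells)
    return {
        "n_outliers_removed": int(len(df.dropna(subset=[value])) - len(clean)),
        "wald": fit.wald_table.to_dict("records"),
        "alpha": fit.alpha,
        "converged": bool(fit.converged),
        "posthoc": posthoc.to_dict("records"),
        "recovery": _fold_recovery(clean, value, truth_folds),
    }


@dataclass
class RunManifest:
    seed: int
    version: str
    config: dict
    file_hashes: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)


def run_full_study(config: GeneratorConfig,
                   outdir: str | Path | None = None,
                   ) -> tuple[RunManifest, dict]:
    """Run the whole synthetic study and return (manifest, report).

    The report holds the six analysis blocks plus the distance models; with
    ``outdir`` set, the generated study, the report (JSON) and the manifest
    are also written to disk.
    """
    t0 = time.perf_counter()
    manifest = RunManifest(seed=config.seed, version=__version__,
                           config=config.to_dict())
    study = generate_study(config)
    manifest.timings_s["generate"] = time.perf_counter() - t0

    t1 = time.perf_counter()
    dcx = dcx_table(study)
    rod = bdnf_rod_table(study)
    vols = volume_table(study)
    dists = distance_table(study)
    mrna = mrna_table(study)
    prot = protein_table(study)
    manifest.timings_s["quantify"] = time.perf_counter() - t1

    t2 = time.perf_counter()
    cfg = config
    fold = cfg.dcx_fold_enriched
    report: dict = {"seed": cfg.seed, "version": __version__}
    report["dcx_ihc"] = _analysis_block(dcx, "normalized", cfg, fold)
    report["dcx_mrna"] = _analysis_block(mrna, "normalized_dcx", cfg, fold)
    report["dcx_protein"] = _analysis_block(
        prot, "normalized_dcx", cfg, cfg.protein_fold)
    rod_mean = (rod.groupby(["animal_id", "region", "treatment",
                             "cage_id"], as_index=False)["rod_corrected"]
                .mean())
    report["bdnf_ihc"] = _analysis_block(
        rod_mean, "rod_corrected", cfg, {r: 1.0 for r in ("dorsal",
                                                          "ventral")})
    report["bdnf_mrna"] = _analysis_block(
        mrna, "normalized_bdnf", cfg, {r: 1.0 for r in ("dorsal",
                                                        "ventral")})
    vol_sum = (vols.groupby(["animal_id", "region", "treatment", "cage_id",
                             "staining_method"], as_index=False)
               ["volume_mm3"].sum())
    report["volumes"] = _analysis_block(
        vol_sum, "volume_mm3", cfg,
        {"dorsal": 1.0 + cfg.volume_effect_dorsal, "intermediate": 1.0,
         "ventral": 1.0},
        extra_terms=" + staining_method")

    # running-distance coupling, enriched PCR-arm animals
    mrna_e = mrna[mrna["treatment"] == "E"].merge(dists, on="animal_id")
    report["bdnf_distance_r2"] = dgstats.covariate_r2(
        mrna_e, "normalized_bdnf", "distance_km", by="region")
    manifest.timings_s["analyze"] = time.perf_counter() - t2

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = write_study(study, outdir)
        for name, path in paths.items():
            manifest.file_hashes[name] = hashlib.sha256(
                path.read_bytes()).hexdigest()
        report_json = json.dumps(report, indent=2, sort_keys=True)
        (outdir / "report.json").write_text(report_json)
        manifest.file_hashes["report.json"] = hashlib.sha256(
            report_json.encode()).hexdigest()
        (outdir / "manifest.json").write_text(
            json.dumps(vars(manifest), indent=2, sort_keys=True, default=str))
    return manifest, report


# ---------------------------------------------------------------------------
# input validation

REQUIRED_COLUMNS = {
    "animals.csv": ["animal_id", "batch", "cage_id", "treatment", "arm"],
    "outlines.csv": ["animal_id", "region", "subfield",
                     "section_position_um", "area_um2", "spacing_to_next_um"],
    "activity.csv": ["cage_id", "day", "total_spins", "hour", "animal_id",
                     "observed_seconds"],
    "expression.csv": ["animal_id", "region", "modality", "gene", "measure",
                       "value"],
    "standards.csv": ["gene", "quantity", "cq"],
}


def validate_inputs(root: str | Path) -> list[str]:
    """Schema and geometry checks for a study directory; returns errors."""
    import tifffile

    root = Path(root)
    errors: list[str] = []
    for name, cols in REQUIRED_COLUMNS.items():
        path = root / name
        if not path.exists():
            continue
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # malformed CSV
            errors.append(f"{name}: unreadable ({exc})")
            continue
        missing = [c for c in cols if c not in df.columns]
        if missing:
            errors.append(f"{name}: missing required column(s) {missing}")
    images = root / "images"
    if images.is_dir():
        for img_path in sorted(images.glob("*.tif")):
            if img_path.stem.endswith("_mask"):
                continue
            mask_path = images / f"{img_path.stem}_mask.tif"
            if not mask_path.exists():
                errors.append(f"{img_path.name}: no matching mask image")
                continue
            img = tifffile.imread(img_path)
            msk = tifffile.imread(mask_path)
            if img.shape != msk.shape:
                errors.append(f"{img_path.name}: mask shape {msk.shape} "
                              f"does not match image shape {img.shape}")
    return errors
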