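# dgquant

Quantification and repeated-measures inference for studies of adult
hippocampal neurogenesis along the dorso-ventral (septo-temporal) axis of
the mouse dentate gyrus (DG), together with a seeded synthetic-study
generator that carries exact ground truth for every estimator.

The scientific setting: short environmental enrichment changes neurogenesis
markers region-specifically — doublecortin (DCX, a marker of immature
neurons) rises in the dorsal DG and falls in the ventral DG, while BDNF in
the ventral DG couples to how much each mouse actually runs. Measuring this
requires a chain of estimators, each of which this package implements as a
tested, reusable operation:

- **histo** — DCX⁺ area fraction of the granule cell layer (GCL) by
  per-section adaptive DAB thresholding: `threshold = mean − 2·SD` of a
  stain-free reference region, positives strictly darker than threshold,
  areas pooled over frames → sections → hemispheres before dividing:
  `DCX_norm = Σ DCX area / Σ GCL area`.
- **densitometry** — BDNF relative optical density `OD = log10(255/gray)`
  averaged over four DG sampling sites (suprapyramidal, infrapyramidal,
  hilus, mossy fibers), corrected by subtracting each section's
  corpus-callosum OD.
- **volumetry** — Cavalieri volumes from serial outlines,
  `V = Σᵢ Aᵢ·sᵢ` with the last section contributing `A·240 µm`
  (configurable to the sampling interval instead).
- **activity** — per-mouse running distance from cage-level wheel counts:
  observed running seconds in sampled 3-minute video windows give activity
  proportions; daily spins are allocated by the renormalized shares
  `tᵢ/Σⱼtⱼ` (conserving the counted total exactly) and converted to km via
  the wheel circumference.
- **molecular** — qPCR standard curves `Cq = a + b·log10(q)` with
  efficiency `10^(−1/b) − 1`, quantification by inversion, and expression
  normalized to *Prox1* (a pan-granule-cell transcription factor), so
  ratios measure expression per granule cell.
- **stats** — IQR(2.2) outlier screening, Gaussian identity-link GEE with
  exchangeable working correlation and robust sandwich covariance
  (animals are clusters; regions are repeated measures), Wald χ² tests,
  unadjusted (LSD) pairwise cell comparisons, and per-region r² for
  running-distance covariates.
- **synth** — generates a full study (cohort of 96 mice in 4 batches, 3 per
  cage, one mouse per cage per assay arm; section images with exact
  positive-pixel counts; outline stacks whose Cavalieri sum equals the true
  volume; activity logs; Cq/ELISA tables) with every true value stored in
  sidecar tables.
- **pipeline** — one-command generate → quantify → analyze → report runs
  with a reproducibility manifest.

## Worked example

```bash
dgquant run --seed 1 --out run1
```

generates a complete synthetic study (default effect sizes: DCX staining
×1.4 dorsal and ÷1.4 ventral under enrichment, DCX protein ×1.6 / ÷1.2,
dorsal volumes +15%, ventral Bdnf–distance r² 0.535), quantifies every
modality, fits the GEE models, and prints the recovered enrichment folds
next to their ground truth:

```
dcx_ihc      dorsal       fold 1.317 (truth 1.400)
dcx_ihc      ventral      fold 0.805 (truth 0.714)
dcx_mrna     dorsal       fold 1.363 (truth 1.400)
dcx_mrna     ventral      fold 0.726 (truth 0.714)
dcx_protein  dorsal       fold 1.527 (truth 1.600)
dcx_protein  ventral      fold 0.911 (truth 0.833)
bdnf_ihc     dorsal       fold 1.000 (truth 1.000)
bdnf_ihc     ventral      fold 1.000 (truth 1.000)
bdnf_mrna    dorsal       fold 0.954 (truth 1.000)
bdnf_mrna    ventral      fold 0.943 (truth 1.000)
volumes      dorsal       fold 1.131 (truth 1.150)
volumes      intermediate fold 0.969 (truth 1.000)
volumes      ventral      fold 0.936 (truth 1.000)
```

Each fold is the ratio of cohort means (enriched/control) for one region;
single-cohort estimates scatter around truth with the configured biological
noise. `run1/report.json` holds the six analysis blocks (Wald χ² tables,
LSD pairwise comparisons, recovery tables) — for this seed the DCX
immunohistochemistry block gives treatment×region χ²(1) = 45.2, p < 0.001,
the signature crossover interaction — plus the per-region Bdnf–distance
r² (ventral 0.596, dorsal 0.00003 here). Stage-level subcommands
(`dgquant dcx|rod|volume|distance|express|stats|generate|validate`) operate
on the documented CSV/TIFF exchange formats; see `dgquant --help`.

As a library:

```python
from dgquant.config import GeneratorConfig
from dgquant.synth import generate_study
from dgquant import pipeline, stats

study = generate_study(GeneratorConfig(seed=1))
dcx = pipeline.dcx_table(study)          # per animal x region, normalized
fit = stats.gee_fit(dcx, "normalized ~ treatment * region",
                    groups="animal_id")
print(fit.wald_table)
```

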