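# Methods

This note documents the models and procedures implemented in `dgquant`,
the assumptions behind the synthetic-data generator, the numerical
conventions, and the known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Study design

The emulated design is a cohort of 96 female mice run in 4 batches of 24,
housed 3 per cage; within each batch half the cages are assigned to an
enriched environment (E: larger cage, three counted running wheels, video
monitoring) and half to standard housing (C). Each cage contributes exactly
one mouse to each assay arm — immunohistochemistry (IHC), RT-PCR, ELISA —
so every arm holds 16 mice per treatment with one mouse per cage, keeping
cage a between-animal factor. Enriched mice carry one of three hair-dye
mark patterns for video identification. IHC-arm brains are split evenly
between cresyl-violet and antibody counterstain for the volumetry slides,
and the staining method is carried into the volume model as a categorical
covariate because the two stains resolve dorsal boundaries differently.

## Quantification models

### DCX area fraction (histo)

DAB-stained DCX⁺ structures are darker than tissue. Per section, a
stain-free "clean" region inside the granule cell layer (GCL) provides the
gray statistics for an adaptive threshold

    threshold = mean − 2·SD,

with the sample SD (n−1 denominator; the population convention is a
switch). One threshold per section is computed from the clean ROI of the
section's first frame and applied to every frame of that section's montage
(a per-frame mode exists). A pixel is positive iff it is a GCL pixel with
gray strictly below threshold. Areas are pixel counts × (pixel size)²;
the per-animal, per-region normalized score is the pooled ratio
Σ DCX area / Σ GCL area over frames, sections and hemispheres — not a mean
of per-section ratios — so sections are weighted by the GCL they contain.
Intermediate-region frames are accepted but excluded from the dorsal/
ventral aggregation by default. Default pixel size 0.5 µm (20× capture),
configurable.

**Inherent bias of the threshold rule.** For Gaussian background noise the
mean−2SD rule classifies Φ(−2) ≈ 2.28% of genuinely unstained GCL pixels
as positive, independent of the noise SD (the threshold scales with it).
The estimated fraction is therefore ≈ f + 0.023·(1−f), which attenuates
between-group fold changes: with the default generator fractions the
configured 1.4-fold effects are recovered as ≈1.36 (dorsal) and ≈1.31
(ventral), as the acceptance benchmarks measure. At zero background noise
the estimator is exact (verified by test). This bias is a property of the
published thresholding rule, not of its implementation; it is left intact
deliberately.

### BDNF densitometry

BDNF staining is diffuse, so darkness is quantified instead of area:
uncalibrated per-pixel optical density `OD = log10(255 / max(gray, 1))`
(gray 0 clamped to 1, capping OD at ≈2.407), averaged over four manually
outlined rectangular sites per section: suprapyramidal blade,
infrapyramidal blade, hilus, mossy fibers. The mean OD of the corpus
callosum on the same section is subtracted before averaging over a brain's
sections, removing section-wide background and illumination shifts (a
uniform OD offset of a whole section cancels up to 8-bit quantization,
≤0.01 OD; verified by test). Negative corrected values are retained. A
step-tablet OD calibration is out of scope; only relative densities are
interpreted.

### Cavalieri volumetry

Dorsal hippocampal fields are outlined every 480 µm, intermediate and
ventral fields every 240 µm, DG and CA separately, hemispheres pooled.
The volume is V = Σᵢ Aᵢ·sᵢ with sᵢ the distance to the next section and
the *last* section contributing A·240 µm regardless of the stack's
sampling interval — the rule as originally stated, applied verbatim even
to 480-µm dorsal stacks. Because that is faithful but odd,
`last_section_rule="interval"` switches the last term to the stack's own
spacing. Volumes are reported in mm³.

### Running-distance allocation

Cage wheel counters record one daily spin total for three mice. The first
3 minutes of every recorded hour are scored for per-mouse running seconds.
With tᵢ the summed seconds for mouse i and T the time at least one mouse
ran, the proportions pᵢ = tᵢ/T can sum above 1 (mice share wheels), so the
day's spins are allocated by the renormalized shares pᵢ/Σⱼpⱼ = tᵢ/Σⱼtⱼ,
which conserves the counted total exactly; fractional spins are kept
unrounded for the same reason. T itself cancels from the shares; since the
union running time is not recoverable from per-mouse totals, the
implementation uses the lower bound Σ_w max_i(s_wi), which only matters
for flagging days with counted spins but no observed running (an error by
default; an equal split is opt-in). Distance = spins × circumference
(default 0.38 m — not stated in the source protocol, configurable) / 1000,
in km.

### Molecular normalization

qPCR uses absolute quantification against serial dilutions of purified
standards: Cq = a + b·log10(q) fitted by least squares (at least three
distinct dilutions; a non-negative slope is rejected), efficiency
10^(−1/b) − 1, unknowns inverted through the curve. Reactions are
singlicate, as in the emulated protocol. Expression of Dcx and Bdnf is
reported relative to Prox1, expressed by every dentate granule cell, making
ratios a per-granule-cell measure and cancelling extraction and
reverse-transcription efficiency (multiplying all quantities of a sample by
a constant leaves ratios unchanged; verified by test). ELISA quantities
skip the curve and are normalized identically.

### Statistics

Values are screened per treatment×region cell by the interquartile-range
rule with fences Q1 − 2.2·IQR and Q3 + 2.2·IQR (quartiles by linear
interpolation, the type-7 convention; cells under four observations are
left unscreened), with an audit table of exclusions. Inference uses
generalized estimating equations: Gaussian family, identity link, animals
as clusters, regions as repeated measures, exchangeable working correlation
by default (independence available; it reproduces OLS to 1e-8). The
iteration alternates weighted least squares for β with moment re-estimation
of the exchangeable α from within-cluster products of Pearson residuals
(singleton clusters contribute nothing; all-singleton data give α = 0),
stopping at max|Δβ| < 1e-8 or 100 iterations. The reported covariance is
the robust sandwich estimator; effects are tested by Wald χ² with
df = rank of the contrast. Pairwise cell comparisons use unadjusted Wald z
(least-significant-difference convention — no multiplicity adjustment
beyond the omnibus gate). Ratios are analyzed untransformed, as plotted in
this literature. Distance covariate effects are accompanied by per-region
squared Pearson correlations (groups under three observations omitted).
The implementation was verified against statsmodels' GEE (coefficients, α,
and robust SEs agree to 1e-6 on clustered fixtures) but does not depend on
it.

## Synthetic-data generator

Every artifact carries its ground truth in sidecar structures, and every
random draw derives from the study seed plus a stable key (animal id ×
modality), so outputs are byte-reproducible and order-independent.
Multiplicative noise terms are mean-one lognormal (log-mean −σ²/2), making
configured targets unbiased in expectation, not just in the median.

- **DCX frames** (160×160, 8-bit; ~40-row GCL band with an embedded
  20×20-px clean ROI): background gray N(185, 6), stained pixels N(70, 10)
  (well below mean−2SD of the background), 4–6 sections per region. The
  per-frame true stained fraction is control fraction (dorsal 0.20,
  ventral 0.12) × enrichment fold (dorsal 1.4, ventral 1/1.4 for E) ×
  animal (σ=0.15) and frame (σ=0.05) lognormal variation. Soma disks and
  dendrite strokes are stamped until the target count is exceeded, then the
  positive mask is trimmed (or topped up) pixel-wise so the true positive
  count is exact. The absolute fractions are assumptions — the source
  protocol reports only folds — chosen as plausible DCX⁺ GCL area
  fractions.
- **BDNF frames** (128×128): five rectangular ROIs (four sites + corpus
  callosum); site gray encodes true corrected OD (dorsal defaults 0.25 /
  0.18 / 0.10 / 0.26 for supra/infra/hilus/mossy — lowest in the hilus)
  plus a shared per-section background OD drawn from U(0.05, 0.15) that
  the corpus-callosum ROI also carries; ventral sites are darker by a
  configured 0.08 OD. Pixel noise SD 2 gray levels.
- **Outlines**: per region×subfield a target volume (control CA 5.0 / 2.5 /
  3.5 mm³ dorsal/intermediate/ventral; DG = 0.63 / 0.42 / 0.21 of CA;
  dorsal ×1.15 for E; animal σ=0.08 and subfield σ=0.05 lognormal) is drawn,
  and a smooth random area profile is rescaled so its Cavalieri sum under
  the estimator's own last-section rule equals the target exactly — volume
  recovery error is pure cohort noise.
- **Activity**: per-mouse daily spin propensities lognormal(2000 spins/day,
  σ=0.5) with day σ=0.3; the cage total is the rounded sum; each of 12
  hourly dark-phase windows records seconds proportional to the day's true
  shares with observation noise σ=0.25, clipped to [0, 180]. Control cages
  have no wheels and no logs.
- **Expression**: Prox1 lognormal(10, σ=0.25) arbitrary units; Dcx/Prox1
  mRNA base 0.8 dorsal / 1.2 ventral (higher ventrally) × folds for E;
  protein base 1.0 × folds 1.6 / 1:1.2; ratio noise σ=0.18. Ventral
  Bdnf/Prox1 of enriched animals is linear in the true distance with the
  residual SD variance-budgeted against the Cq measurement noise so that
  the squared correlation at the *measured* level targets 0.535; dorsal
  Bdnf is independent of running. PCR-arm tables are Cq values (per-gene
  standard curves with efficiencies drawn from 98–104%, sample Cq SD 0.12,
  standards SD 0.05); ELISA tables are quantities with CV 8%.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: anatomically realistic DG geometry and
stain morphology, section damage and fold artifacts, staining-batch drift
beyond per-section offsets, observer disagreement in video scoring beyond
window noise, qPCR inhibition or melt-curve failures, and any systematic
difference between cresyl and antibody volume outlines (the covariate is
carried but no effect is injected by default). Recovery results show that
the estimators are correct for data satisfying the stated noise models, at
the stated design scale.

## Numerical conventions and degenerate inputs

Strict inequality at the threshold boundary (a pixel exactly at threshold
is negative); clean ROIs under two pixels, empty GCL masks, zero Prox1,
zero CA volumes, duplicate section positions, non-negative standard-curve
slopes, and unattributable activity days all raise typed errors rather
than producing silent values. Unordered outline stacks are reordered with
a warning. RGB inputs are flattened by Rec. 601 luminance weights
(0.299/0.587/0.114), rounded half-up. Gray 0 is clamped to 1 in the OD
transform. Outlier screening never drops NaNs (they are excluded from
modeling separately).

## Benchmark problem sizes

The recovery benchmarks (`dgquant.recovery`, driven by
`scripts/acceptance.py` and the acceptance tests) average over 20 replicate
cohorts for the fold and volume targets and 50 for the distance–expression
correlation, each cohort at the full design scale of 16 animals per
treatment in the relevant arm; the test-calibration benchmark uses 100
replicate cohorts for both the null (type-I error ≤ the nominal band) and
the default-effect (power) configurations. These sizes keep the complete
benchmark suite around a minute on one CPU while bounding the Monte-Carlo
SEM of every reported mean well below the acceptance bands.

## Known limitations

- The mean−2SD positive-area bias discussed above (~+2.3 percentage points
  on stained fractions, fold attenuation ≈0.04–0.09 at default settings).
- The exchangeable GEE sandwich is slightly liberal at 32 clusters (the
  calibration benchmark measures ~7% empirical size at nominal 5%); no
  small-sample covariance correction is applied, matching common practice
  in the emulated analyses.
- Estimated distances attenuate the Bdnf–distance r² by the square of the
  allocation correlation (ρ > 0.9 by test), roughly offset at n=16 by the
  positive finite-sample bias of r²; the acceptance band absorbs both.
- 8-bit quantization bounds densitometry accuracy at ≈0.01 OD.
- The volume generator targets the verbatim last-section rule; estimating
  with the interval rule on generated dorsal stacks shifts volumes by
  design (the rules genuinely differ there).
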