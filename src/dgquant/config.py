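"""Study configuration: cohort design, true effect sizes, and noise levels.

``GeneratorConfig`` is the single seeded description of a synthetic study.
Every generator module draws from it, so a fixed seed reproduces the whole
study byte for byte, and the configured effects are the ground truth that
downstream estimators are scored against.

Units: areas um^2, volumes mm^3, lengths m or um as named, optical density in
log10 absorbance units, expression in arbitrary quantity units (only ratios
to Prox1 are interpreted).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

REGIONS = ("dorsal", "intermediate", "ventral")
DCX_REGIONS = ("dorsal", "ventral")
SUBFIELDS = ("DG", "CA")
ARMS = ("IHC", "PCR", "ELISA")
TREATMENTS = ("E", "C")
BDNF_SITES = ("suprapyramidal", "infrapyramidal", "hilus", "mossy_fibers")

#: mask label conventions shared by the generator and the quantifiers
MASK_BACKGROUND = 0
MASK_GCL = 1
MASK_CLEAN_ROI = 2  # stain-free reference region, a subset of the GCL
MASK_SITE = {"suprapyramidal": 10, "infrapyramidal": 11, "hilus": 12,
             "mossy_fibers": 13}
MASK_CORPUS_CALLOSUM = 20


@dataclass
class GeneratorConfig:
    """Seeded ground-truth description of a synthetic enrichment study.

    Defaults reproduce the reference design: 4 batches of 24 mice (96 total,
    3 per cage, cages split evenly between enriched E and control C housing),
    one third of animals per assay arm, a 1.4-fold dorsal increase /
    1.4-fold ventral decrease in DCX staining under enrichment, a 1.6-fold
    dorsal increase / 1.2-fold ventral decrease in DCX protein, 15% larger
    dorsal hippocampal volumes, DG/CA volume ratios of 0.63/0.42/0.21
    (dorsal/intermediate/ventral), and a ventral Bdnf/Prox1 vs. running
    distance coupling with r^2 = 0.535.
    """

    seed: int = 0

    # -- cohort design ------------------------------------------------------
    n_batches: int = 4
    animals_per_batch: int = 24
    mice_per_cage: int = 3

    # -- DCX immunohistochemistry -------------------------------------------
    #: true stained fraction of GCL pixels, control animals
    dcx_fraction_control: dict[str, float] = field(
        default_factory=lambda: {"dorsal": 0.20, "ventral": 0.12})
    #: multiplicative enrichment effect on the stained fraction
    dcx_fold_enriched: dict[str, float] = field(
        default_factory=lambda: {"dorsal": 1.4, "ventral": 1 / 1.4})
    #: between-animal lognormal sigma of the stained fraction
    dcx_animal_sigma: float = 0.15
    #: between-frame lognormal sigma within one animal
    dcx_frame_sigma: float = 0.05
    dcx_sections_min: int = 4
    dcx_sections_max: int = 6
    frame_shape: tuple[int, int] = (160, 160)
    pixel_size_um_dcx: float = 0.5   # emulated 20x capture
    pixel_size_um_bdnf: float = 1.0  # emulated 10x capture
    #: tissue background and stained-pixel gray-value distributions
    bg_mean_gray: float = 185.0
    bg_sd_gray: float = 6.0
    pos_mean_gray: float = 70.0
    pos_sd_gray: float = 10.0

    # -- BDNF densitometry --------------------------------------------------
    #: true background-corrected OD per site, dorsal sections
    bdnf_site_od_dorsal: dict[str, float] = field(
        default_factory=lambda: {"suprapyramidal": 0.25, "infrapyramidal": 0.18,
                                 "hilus": 0.10, "mossy_fibers": 0.26})
    #: additive OD excess of every ventral site over its dorsal counterpart
    bdnf_rod_ventral_excess: float = 0.08
    bdnf_sections_per_region: int = 4
    #: per-section shared background OD range (removed by correction)
    bdnf_background_od_range: tuple[float, float] = (0.05, 0.15)
    bdnf_pixel_gray_sd: float = 2.0

    # -- volumetry ----------------------------------------------------------
    #: true CA volume per region, control animals, hemispheres combined (mm^3)
    ca_volume_mm3: dict[str, float] = field(
        default_factory=lambda: {"dorsal": 5.0, "intermediate": 2.5,
                                 "ventral": 3.5})
    #: DG volume as a fraction of CA volume, per region
    dgca_ratio: dict[str, float] = field(
        default_factory=lambda: {"dorsal": 0.63, "intermediate": 0.42,
                                 "ventral": 0.21})
    #: relative enrichment effect on dorsal volumes (DG and CA alike)
    volume_effect_dorsal: float = 0.15
    #: between-animal lognormal sigma of the overall volume scale
    volume_animal_sigma: float = 0.08
    #: additional per-subfield lognormal sigma
    volume_subfield_sigma: float = 0.05
    sections_dorsal: int = 7
    sections_other: int = 6
    spacing_dorsal_um: float = 480.0
    spacing_other_um: float = 240.0

    # -- wheel running ------------------------------------------------------
    wheel_circumference_m: float = 0.38
    days: int = 8
    windows_per_day: int = 12          # hourly 3-min samples, dark phase
    window_seconds: float = 180.0
    #: lognormal(log-mean, sigma) of per-mouse daily spin propensity
    propensity_mean_spins: float = 2000.0
    propensity_sigma: float = 0.5
    daily_sigma: float = 0.3
    observation_sigma: float = 0.25

    # -- molecular ----------------------------------------------------------
    prox1_mean_qty: float = 10.0
    prox1_sigma: float = 0.25
    #: control-animal Dcx/Prox1 mRNA ratio per region
    dcx_mrna_base: dict[str, float] = field(
        default_factory=lambda: {"dorsal": 0.8, "ventral": 1.2})
    #: control-animal Bdnf/Prox1 mRNA ratio per region
    bdnf_mrna_base: dict[str, float] = field(
        default_factory=lambda: {"dorsal": 0.6, "ventral": 0.9})
    #: control-animal DCX/PROX1 protein ratio per region
    dcx_protein_base: dict[str, float] = field(
        default_factory=lambda: {"dorsal": 1.0, "ventral": 1.0})
    #: enrichment effect on the protein ratio
    protein_fold: dict[str, float] = field(
        default_factory=lambda: {"dorsal": 1.6, "ventral": 1 / 1.2})
    #: between-animal lognormal sigma on expression ratios
    ratio_sigma: float = 0.18
    #: target squared correlation of ventral Bdnf/Prox1 with distance (E only)
    bdnf_distance_r2_ventral: float = 0.535
    #: SD of the distance signal in Bdnf/Prox1 ratio units
    bdnf_distance_signal_sd: float = 0.25
    #: qPCR standard-curve efficiency range (fraction, 1.0 = 100%)
    efficiency_range: tuple[float, float] = (0.98, 1.04)
    cq_sd: float = 0.12
    cq_sd_standards: float = 0.05
    standards_decades: int = 6
    elisa_cv: float = 0.08

    # -- analysis conventions (switchable) ----------------------------------
    threshold_sd_multiplier: float = 2.0
    threshold_sd_ddof: int = 1             # sample SD convention
    last_section_rule: str = "fixed"       # "fixed" (always 240 um) or "interval"
    iqr_multiplier: float = 2.2
    working_correlation: str = "exchangeable"

    # ------------------------------------------------------------------

    @property
    def cages_per_batch(self) -> int:
        return self.animals_per_batch // self.mice_per_cage

    def validate(self) -> None:
        """Raise ``InvalidDesignError``/``ValueError`` on inconsistencies."""
        if self.animals_per_batch % self.mice_per_cage:
            raise InvalidDesignError(
                f"animals_per_batch={self.animals_per_batch} is not divisible "
                f"by mice_per_cage={self.mice_per_cage}")
        if self.cages_per_batch % 2:
            raise InvalidDesignError(
                f"{self.cages_per_batch} cages per batch cannot be split "
                "evenly between enriched and control housing")
        for name in ("dcx_fraction_control",):
            for region, frac in getattr(self, name).items():
                if not 0.0 <= frac < 1.0:
                    raise ValueError(f"{name}[{region}]={frac} not in [0, 1)")
        for name in ("dcx_fold_enriched", "protein_fold", "dgca_ratio"):
            for region, fold in getattr(self, name).items():
                if fold <= 0:
                    raise ValueError(f"{name}[{region}]={fold} must be > 0")
        for region in DCX_REGIONS:
            eff = (self.dcx_fraction_control[region]
                   * self.dcx_fold_enriched[region])
            if eff >= 1.0:
                raise InvalidConfigError(
                    f"enriched {region} stained fraction {eff:.3f} >= 1")
        for region, vol in self.ca_volume_mm3.items():
            if vol <= 0:
                raise InvalidConfigError(f"ca_volume_mm3[{region}]={vol} <= 0")
        if self.wheel_circumference_m <= 0:
            raise ValueError("wheel_circumference_m must be positive")
        if not 0 < self.bdnf_distance_r2_ventral < 1:
            raise ValueError("bdnf_distance_r2_ventral must be in (0, 1)")
        if self.last_section_rule not in ("fixed", "interval"):
            raise ValueError("last_section_rule must be 'fixed' or 'interval'")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        # tuples (ranges, shapes) round-trip through YAML as lists
        kwargs = {k: tuple(v) if isinstance(v, list) else v
                  for k, v in d.items()}
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def null(self) -> "GeneratorConfig":
        """A copy with every treatment effect switched off.

        Used for type-I-error calibration: enriched and control animals are
        then exchangeable in every modality.
        """
        cfg = dataclasses.replace(self)
        cfg.dcx_fold_enriched = {r: 1.0 for r in cfg.dcx_fold_enriched}
        cfg.protein_fold = {r: 1.0 for r in cfg.protein_fold}
        cfg.volume_effect_dorsal = 0.0
        return cfg


class InvalidDesignError(ValueError):
    """Cohort design constraints cannot be satisfied."""


class InvalidConfigError(ValueError):
    """A configured ground-truth value is physically impossible."""
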