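"""Configuration dataclasses for simulation, filtering and the pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its documented invariants."""


@dataclass
class FixedEffects:
    """Fixed-effect sizes used by the phenotype simulator.

    Germination time (GT) effects are in hours; germination-rate (GR)
    effects act on the logit (liability) scale.  Signs follow the field
    convention: negative ``gt_temperature`` means warm-treated seeds
    germinate faster, negative ``gr_type_wild`` means wild accessions
    germinate less often than landraces.
    """

    gt_intercept: float = 60.0          # hours, cold-grown landrace baseline
    gt_temperature: float = -16.0       # warm minus cold, hours
    gt_type_wild: float = 25.92         # wild minus landrace, hours
    gt_batch_sd: float = 2.0            # SD of per-batch shifts, hours
    gt_year: float = 2.0                # second multiplication year, hours
    gt_conservation: float = 0.01       # hours per day of storage
    gr_intercept: float = 2.2           # logit scale
    gr_temperature: float = 0.4
    gr_type_wild: float = -2.5
    gr_batch_sd: float = 0.15
    gr_year: float = -0.2
    gr_conservation: float = -0.002     # per day, interacts with temperature
    gr_conservation_x_temp: float = -0.001
    emergence_intercept: float = 1.0    # logit scale
    emergence_gamma: float = 0.8        # loading of E on the GR genetic value
    emergence_noise_sd: float = 0.3


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a single-species accession panel: ~100 accessions in a
    few ancestral clusters (the wild/landrace structure), two controlled
    germination temperatures, right-censoring of germination time at 168 h,
    and an intermediate narrow-sense heritability (sigma2_g/(sigma2_g +
    sigma2_e) = 0.3).
    """

    n_accessions: int = 100
    n_snps: int = 2000
    k_pops: int = 3
    fst: float = 0.3
    admixture_concentration: float = 0.2
    hard_split: bool = False            # assign accessions to pops in equal blocks
    seeds_per_cell: int = 50            # seeds per accession x temperature
    temperatures: tuple = (("cold", 20.0), ("warm", 35.0))
    fixed_effects: FixedEffects = field(default_factory=FixedEffects)
    sigma2_g: float = 75.0              # additive variance of GT, hours^2
    sigma2_e: float = 175.0             # residual variance of GT, hours^2
    sigma2_g_liability: float = 0.5     # additive variance on the GR logit scale
    ge_correlation: float = 0.8         # cross-temperature genetic correlation
    latitude_slope: float = 0.0         # effect on warm values per degree latitude
    latitude_range: tuple = (35.0, 60.0)
    n_batches: int = 8
    years: tuple = ("2020/2021", "2021/2022")
    conservation_range: tuple = (100.0, 900.0)
    censor_hours: float = 168.0
    gt_distribution: str = "gaussian"   # or "lognormal"
    species: str = "rapa"
    countries: tuple = ("France", "Italy", "Algeria", "Spain", "Slovenia", "Tunisia")
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fst < 1.0):
            raise ConfigurationError(f"fst must be in (0,1), got {self.fst}")
        if self.k_pops < 1:
            raise ConfigurationError("k_pops must be >= 1")
        if not (-1.0 <= self.ge_correlation <= 1.0):
            raise ConfigurationError("ge_correlation must be in [-1, 1]")
        if self.sigma2_g < 0 or self.sigma2_e < 0 or self.sigma2_g_liability < 0:
            raise ConfigurationError("variance components must be non-negative")
        if self.n_accessions < 2:
            raise ConfigurationError("need at least 2 accessions")
        if self.n_snps < 1:
            raise ConfigurationError("need at least 1 SNP")
        labels = [t[0] for t in self.temperatures]
        if len(labels) != 2 or labels[0] == labels[1]:
            raise ConfigurationError("temperatures must be two distinct labels")
        if isinstance(self.fixed_effects, dict):
            self.fixed_effects = FixedEffects(**self.fixed_effects)
        if self.gt_distribution not in ("gaussian", "lognormal"):
            raise ConfigurationError("gt_distribution must be gaussian or lognormal")

    @property
    def temperature_labels(self) -> list:
        return [t[0] for t in self.temperatures]

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class FilterConfig:
    """Thresholds of the post-calling site/sample filters."""

    min_accession_mean_depth: float = 20.0   # strict ">": exactly 20 is dropped
    indel_distance_bp: int = 5               # SNPs < 5 bp from an indel removed
    depth_lo_pct: float = 5.0
    depth_hi_pct: float = 95.0
    min_mq: float = 40.0                     # strict ">": MQ == 40 is dropped
    min_allele_depth: int = 10
    chromosome_names: tuple = tuple(f"A{i:02d}" for i in range(1, 11))
    ld_r2_max: float = 0.2
    ld_window: int = 1000
    ld_window_unit: str = "sites"            # "sites" (bcftools -w literal) or "bp"
    percentile_method: str = "linear"        # numpy interpolation method

    def __post_init__(self) -> None:
        if not self.chromosome_names:
            raise ConfigurationError("chromosome_names must be non-empty")
        if self.ld_window_unit not in ("sites", "bp"):
            raise ConfigurationError("ld_window_unit must be 'sites' or 'bp'")

    @classmethod
    def from_yaml(cls, path) -> "FilterConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})


@dataclass
class PipelineConfig:
    """Single configuration driving the end-to-end pipeline."""

    out_dir: str = "germtherm_out"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    vcf_path: str | None = None              # use an existing VCF instead of simulating
    phenotype_csv: str | None = None
    emergence_csv: str | None = None
    residual_type: str = "working"           # latent residual for GRA
    gt_suites: tuple = ("1", "1b", "1c")
    gra_suites: tuple = ("3", "3b", "3c", "3d")
    rng_seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(
                **{k: tuple(v) if isinstance(v, list) else v for k, v in self.simulation.items()}
            )
        if isinstance(self.filters, dict):
            self.filters = FilterConfig(
                **{k: tuple(v) if isinstance(v, list) else v for k, v in self.filters.items()}
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def resolve(self, base: Path) -> "PipelineConfig":
        """Resolve relative paths against ``base``."""
        cfg = dataclasses.replace(self)
        for name in ("vcf_path", "phenotype_csv", "emergence_csv"):
            val = getattr(cfg, name)
            if val is not None and not Path(val).is_absolute():
                setattr(cfg, name, str(base / val))
        return cfg
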