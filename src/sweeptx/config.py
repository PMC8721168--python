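"""Pipeline configuration: YAML-backed, validated in one pass.

Parameter defaults are the scan's canonical values: 40-kb windows with
20-kb steps, joint top-5% outliers, Phred-20 quality floor, 5-bp SNP
spacing, depth kept within [1/3, 5] x mean, 1,000 bootstrap replicates,
and the fold-change > 2 / < 0.5 with p < 0.05 DEG rule.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigError


class SweepRegionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    chrom: str
    start: int = Field(ge=0)
    end: int = Field(gt=0)
    selected_pop: str
    diversity_reduction: float = Field(default=0.2, gt=0.0, le=1.0)
    differentiation_boost: float = Field(default=0.3, ge=0.0, le=1.0)


class RnaSeqSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_genes: int = Field(default=2000, gt=0)
    n_per_group: int = Field(default=4, ge=2)
    mean_log_expression: float = 4.0
    sd_log_expression: float = Field(default=1.0, ge=0.0)
    dispersion: float = Field(default=0.1, ge=0.0)
    n_de: int = Field(default=200, ge=0)
    lfc_de: float = Field(default=2.0, ge=0.0)


class SimulateSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_pops: int = Field(default=2, ge=1)
    samples_per_pop: int = Field(default=8, ge=2)
    chrom_lengths: dict[str, int] = Field(default_factory=lambda: {"chr1": 10_000_000})
    n_snps: int = Field(default=100_000, gt=0)
    fst_background: float = Field(default=0.05, ge=0.0, lt=1.0)
    sweep_regions: list[SweepRegionConfig] = Field(default_factory=list)
    rnaseq: RnaSeqSection = Field(default_factory=RnaSeqSection)
    mean_depth: float = Field(default=120.0, gt=0.0)
    depth_overdispersion: float = Field(default=0.3, ge=0.0)
    frac_low_qual: float = Field(default=0.0, ge=0.0, le=1.0)
    missing_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    pop_names: list[str] | None = None


class InputsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    vcf: str
    sample_map: str
    gff: str
    counts: str
    group_map: str
    mapped_reads: str


class ParamsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    window_size: int = Field(default=40_000, gt=0)
    window_step: int = Field(default=20_000, gt=0)
    top_fraction: float = Field(default=0.05, gt=0.0, le=1.0)
    min_qual: float = Field(default=20.0, ge=0.0)
    min_spacing: int = Field(default=5, ge=0)
    depth_low_mult: float = Field(default=1.0 / 3.0, gt=0.0)
    depth_high_mult: float = Field(default=5.0, gt=0.0)
    n_boot: int = Field(default=1000, ge=1)
    fc_hi: float = Field(default=2.0, gt=0.0)
    fc_lo: float = Field(default=0.5, gt=0.0)
    alpha: float = Field(default=0.05, gt=0.0, le=1.0)
    use_adjusted_p: bool = False
    fst_estimator: Literal["wc", "hudson"] = "wc"
    min_snps_per_window: int = Field(default=1, ge=0)
    shared_deg_rule: Literal["intersection", "union"] = "intersection"
    distance_metric: Literal["allele_sharing", "ibs"] = "allele_sharing"
    pca_components: int = Field(default=10, ge=1)

    @model_validator(mode="after")
    def _check_ranges(self) -> "ParamsSection":
        if self.window_size < self.window_step:
            raise ValueError("window_size must be >= window_step")
        if self.depth_high_mult <= self.depth_low_mult:
            raise ValueError("depth_high_mult must exceed depth_low_mult")
        if self.fc_hi <= self.fc_lo:
            raise ValueError("fc_hi must exceed fc_lo")
        return self


class ComparisonConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    selected: str
    control: str


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = Field(default=0, ge=0, lt=2**31)
    outdir: str = "results/pipeline"
    simulate: SimulateSection | None = None
    inputs: InputsSection | None = None
    params: ParamsSection = Field(default_factory=ParamsSection)
    comparisons: list[ComparisonConfig] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either a 'simulate' or an 'inputs' section")
        if self.simulate is not None:
            sim = self.simulate
            pop_names = sim.pop_names or [f"pop{i + 1}" for i in range(sim.n_pops)]
            for r in sim.sweep_regions:
                if r.selected_pop not in pop_names:
                    raise ValueError(f"sweep region selects unknown population "
                                     f"{r.selected_pop!r} (known: {pop_names})")
                if r.chrom not in sim.chrom_lengths:
                    raise ValueError(f"sweep region on unknown chromosome {r.chrom!r}")
            for c in self.comparisons:
                for p in (c.selected, c.control):
                    if p not in pop_names:
                        raise ValueError(f"comparison references unknown population {p!r}")
        return self


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config, reporting all errors at once."""
    try:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    try:
        return PipelineConfig.model_validate(raw)
    except Exception as exc:  # pydantic.ValidationError lists every failure
        msgs = []
        errors = getattr(exc, "errors", None)
        if callable(errors):
            for e in errors():
                loc = ".".join(str(x) for x in e["loc"])
                msgs.append(f"{loc or '<root>'}: {e['msg']}")
        raise ConfigError("invalid config:\n  " + "\n  ".join(msgs or [str(exc)])) from exc


def sim_config_from(cfg: PipelineConfig):
    """Build a :class:`~sweeptx.synthetic_data.SimConfig` from the pipeline config."""
    from .synthetic_data import RnaSeqConfig, SimConfig, SweepRegion

    if cfg.simulate is None:
        raise ConfigError("config has no 'simulate' section")
    s = cfg.simulate
    return SimConfig(
        seed=cfg.seed,
        n_pops=s.n_pops,
        samples_per_pop=s.samples_per_pop,
        chrom_lengths=dict(s.chrom_lengths),
        n_snps=s.n_snps,
        fst_background=s.fst_background,
        sweep_regions=[SweepRegion(**r.model_dump()) for r in s.sweep_regions],
        rnaseq=RnaSeqConfig(**s.rnaseq.model_dump()),
        mean_depth=s.mean_depth,
        depth_overdispersion=s.depth_overdispersion,
        frac_low_qual=s.frac_low_qual,
        missing_rate=s.missing_rate,
        window_size=cfg.params.window_size,
        window_step=cfg.params.window_step,
        pop_names=list(s.pop_names) if s.pop_names else None,
    )
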