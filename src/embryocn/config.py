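"""Pipeline configuration: one YAML document, schema-validated.

Every analysis parameter is surfaced with its standard default: 10 kb
native bins, 50 kb granular (deep) or 250 kb (low-pass) working bins,
25%/80% bin-exclusion rule, MAD thresholds 0.15 (low-pass) / 0.3 (deep),
informative-SNP VAF window 40-60%, triploidy statistic window 2.5-3.5 with
correction factor 1.5, SV filters (>=3 reads, MAPQ>30, span >1 Mb,
single-embryo), and the 10 a.u. EdU replication gate.  Unknown keys are
rejected by name.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GenomeConfig(_Strict):
    n_chromosomes: int = 3
    chrom_lengths: list[int] | None = None
    snp_spacing: int = 8_000
    n_hom_sites: int = 0
    seed: int = 0


class EventConfig(_Strict):
    event_class: str
    target_chromosome: str | None = None
    cut_position: int | None = None
    division_index: int | None = None
    affected_haplotype: str | None = None
    mother_index: int = 0
    acentric_fate: str = "replicated"


class CoverageConfig(_Strict):
    mean_depth: float = 9.45
    dispersion: float = 0.05
    repli_bias_strength: float = 0.0
    read_length: int = 100


class SimulateConfig(_Strict):
    genome: GenomeConfig = Field(default_factory=GenomeConfig)
    events: list[EventConfig] = Field(default_factory=list)
    coverage: CoverageConfig = Field(default_factory=CoverageConfig)
    phase: str = "G1"
    with_svs: bool = True
    n_sv_artifacts: int = 20


class InputConfig(_Strict):
    counts: Path | None = None
    allelic_depths: Path | None = None
    repliseq: Path | None = None
    svs: Path | None = None


class TargetSiteConfig(_Strict):
    name: str = "gRNA"
    chromosome: str = "chr1"
    cut_position: int = 30_000_000
    tolerance: int = 1_000_000


class PipelineConfig(_Strict):
    embryo: str = "E1"
    seed: int = 0
    platform: str = "deep"  # "deep" (50 kb working bins) or "low_pass" (250 kb)
    native_bin_size: int = 10_000
    working_bin_size: int | None = None  # defaults by platform
    analysis_bin_size: int = 1_000_000
    low_coverage_fraction: float = 0.25
    low_coverage_sample_fraction: float = 0.80
    mad_thresholds: dict[str, float] = Field(
        default_factory=lambda: {"low_pass": 0.15, "deep": 0.3}
    )
    loess_span: float = 0.3
    cbs_alpha: float = 0.01
    cbs_method: str = "gauss"
    vaf_window: tuple[float, float] = (0.40, 0.60)
    min_covered_samples: int = 3
    # "self": re-derive the informative-SNP panel from the analyzed samples
    # (adequate for large cohorts); "cohort": use the known cross panel,
    # as established on a full cohort, without re-filtering on the embryo
    # at hand (an 8-cell embryo with a whole-chromosome imbalance would
    # bias its own panel).
    panel_source: str = "self"
    half_copy_tolerance: float = 0.15
    sv_min_support: int = 3
    sv_min_mapq: int = 30
    sv_min_span: int = 1_000_000
    sv_presence_threshold: int = 1
    edu_gate: float = 10.0
    target_site: TargetSiteConfig | None = Field(default_factory=TargetSiteConfig)
    simulate: SimulateConfig | None = None
    inputs: InputConfig | None = None

    @property
    def effective_working_bin_size(self) -> int:
        if self.working_bin_size is not None:
            return self.working_bin_size
        return 50_000 if self.platform == "deep" else 250_000


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)
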