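"""Pipeline configuration: a single validated YAML file plus one seed."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .genome import HG19_AUTOSOMES, scaled_autosomes

__all__ = ["PipelineConfig", "load_config", "default_config"]


def _check_range(name, value, lo=None, hi=None, lo_open=False, hi_open=False):
    if lo is not None and (value <= lo if lo_open else value < lo):
        raise ValueError(f"{name}={value} below allowed range")
    if hi is not None and (value >= hi if hi_open else value > hi):
        raise ValueError(f"{name}={value} above allowed range")


@dataclass
class GenomeConfig:
    total_bp: int = 550_000_000
    bin_size: int = 5_000_000
    use_hg19: bool = False
    chrom_lengths: dict | None = None

    def resolve(self) -> dict[str, int]:
        if self.chrom_lengths:
            return {str(k): int(v) for k, v in self.chrom_lengths.items()}
        if self.use_hg19:
            return dict(HG19_AUTOSOMES)
        return scaled_autosomes(self.total_bp)

    def validate(self):
        _check_range("genome.total_bp", self.total_bp, lo=1)
        _check_range("genome.bin_size", self.bin_size, lo=1)


@dataclass
class SimulateConfig:
    n_clones: int = 3
    n_truncal_events: int = 12
    n_private_events: int = 5
    p_wgd: float = 0.0
    deletion_bias: float = 0.6
    clone_proportions: list | None = None
    normal_fraction: float = 0.1
    noise_cell_fraction: float = 0.05
    n_cells: int = 500
    mean_coverage: float = 0.02
    snp_density: float = 1 / 1500
    topology: str = "random"
    min_event_bins: int = 4

    def validate(self):
        _check_range("simulate.n_clones", self.n_clones, lo=1)
        _check_range("simulate.n_truncal_events", self.n_truncal_events, lo=0)
        _check_range("simulate.n_private_events", self.n_private_events, lo=0)
        _check_range("simulate.p_wgd", self.p_wgd, lo=0, hi=1)
        _check_range("simulate.deletion_bias", self.deletion_bias, lo=0, hi=1)
        _check_range("simulate.normal_fraction", self.normal_fraction, lo=0, hi=1, hi_open=True)
        _check_range("simulate.noise_cell_fraction", self.noise_cell_fraction, lo=0, hi=1, hi_open=True)
        _check_range("simulate.n_cells", self.n_cells, lo=1)
        _check_range("simulate.mean_coverage", self.mean_coverage, lo=0, lo_open=True)
        if self.topology not in ("random", "chain", "star"):
            raise ValueError(f"simulate.topology={self.topology!r} unknown")


@dataclass
class InferConfig:
    ploidy_grid: list = field(default_factory=lambda: [1.5, 2.0, 2.5, 3.0, 3.5, 4.0])
    max_cn: int = 8

    def validate(self):
        if not self.ploidy_grid or any(g <= 0 for g in self.ploidy_grid):
            raise ValueError("infer.ploidy_grid must be non-empty and positive")
        _check_range("infer.max_cn", self.max_cn, lo=1)


@dataclass
class ClonesConfig:
    error_rate: float = 0.12
    min_clone_size: int | None = None

    def validate(self):
        _check_range("clones.error_rate", self.error_rate, lo=0, hi=1)


@dataclass
class MetricsConfig:
    wgd_threshold: float = 0.5
    locus: list = field(default_factory=lambda: ["chr17", 7_565_097, 7_590_856])

    def validate(self):
        _check_range("metrics.wgd_threshold", self.wgd_threshold, lo=0, hi=1)


@dataclass
class PhyloConfig:
    allow_wgd: bool = True
    method: str = "exhaustive"

    def validate(self):
        if self.method not in ("exhaustive", "greedy"):
            raise ValueError(f"phylo.method={self.method!r} unknown")


@dataclass
class ConcordConfig:
    bin_size: int = 1000
    mode: str = "allele"
    cluster_threshold: float = 0.3

    def validate(self):
        _check_range("concord.bin_size", self.bin_size, lo=1)
        if self.mode not in ("allele", "total"):
            raise ValueError(f"concord.mode={self.mode!r} unknown")


_SECTIONS = {
    "genome": GenomeConfig,
    "simulate": SimulateConfig,
    "infer": InferConfig,
    "clones": ClonesConfig,
    "metrics": MetricsConfig,
    "phylo": PhyloConfig,
    "concord": ConcordConfig,
}


@dataclass
class PipelineConfig:
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    infer: InferConfig = field(default_factory=InferConfig)
    clones: ClonesConfig = field(default_factory=ClonesConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    phylo: PhyloConfig = field(default_factory=PhyloConfig)
    concord: ConcordConfig = field(default_factory=ConcordConfig)
    seed: int = 0
    outdir: str = "scnakit_run"

    def validate(self):
        for name in _SECTIONS:
            getattr(self, name).validate()
        _check_range("seed", self.seed, lo=0)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        kwargs = {}
        for name, section_cls in _SECTIONS.items():
            sub = raw.pop(name, {}) or {}
            known = {f.name for f in fields(section_cls)}
            unknown = set(sub) - known
            if unknown:
                raise ValueError(f"unknown keys in section {name!r}: {sorted(unknown)}")
            kwargs[name] = section_cls(**sub)
        for key in ("seed", "outdir"):
            if key in raw:
                kwargs[key] = raw.pop(key)
        if raw:
            raise ValueError(f"unknown top-level keys: {sorted(raw)}")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def default_config(**overrides) -> PipelineConfig:
    cfg = PipelineConfig.from_dict(overrides)
    return cfg


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return PipelineConfig.from_dict(raw)
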