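"""End-to-end orchestration: simulate-or-read -> filter -> spectrum -> scan.

A run is described by one declarative configuration (YAML mapping or plain
dict) naming either an input variant file or a simulation block, the sample
roles, and the scan parameters. The run writes all artifacts under one
output prefix and returns a serialisable RunReport whose counts are
internally consistent by construction (and checked).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import yaml

from . import __version__
from .genome import SimulationConfig, default_genome
from .scan import DEFAULT_MORGANS_PER_BP, genome_scan
from .simulate import MUT_SAMPLE, POOL_SAMPLE, WT_SAMPLE, simulate_dataset
from .smooth import SmoothingParams
from .variants import select_markers, spectrum_summary
from .vcfio import (
    read_variant_table,
    write_regions_bed,
    write_track_tsv,
    write_truth_tsv,
    write_vcf,
)

__all__ = ["PipelineConfig", "RunReport", "VariantAccounting", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariantAccounting:
    """SNP/indel decomposition of a variant set; total is always the sum."""

    n_snps: int
    n_indels: int

    @property
    def total(self) -> int:
        return self.n_snps + self.n_indels

    def consistent_with(self, reported_total: int) -> bool:
        return self.total == reported_total


@dataclass
class PipelineConfig:
    input_path: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    wildtype_sample: str = WT_SAMPLE
    mutant_sample: str = MUT_SAMPLE
    pool_sample: str = POOL_SAMPLE
    smoothing: SmoothingParams = field(default_factory=SmoothingParams)
    quantile: float = 0.95
    n_null_sims: int = 100
    pool_size: Optional[int] = 200
    morgans_per_bp: float = DEFAULT_MORGANS_PER_BP
    seed: int = 0
    out_prefix: str = "mutmap_run"
    config_echo: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("exactly one of input_path or simulation must be given")
        names = {self.wildtype_sample, self.mutant_sample, self.pool_sample}
        if len(names) != 3:
            raise ValueError("sample names must be distinct")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = dict(sim)
            if "causal" in sim and sim["causal"] is not None:
                sim["causal"] = (str(sim["causal"][0]), int(sim["causal"][1]))
            sim = SimulationConfig(**sim)
        smoothing = SmoothingParams(**raw.pop("smoothing", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(simulation=sim, smoothing=smoothing, config_echo=dict(raw), **raw)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls.from_dict(raw)
        cfg.config_echo = raw
        return cfg


@dataclass
class RunReport:
    version: str
    seed: int
    n_input_variants: int
    input_accounting: VariantAccounting
    n_markers: int
    n_discarded: int
    marker_accounting: VariantAccounting
    class_counts: dict
    transition_percent: float
    threshold: float
    regions: list
    summit: Optional[dict]
    config_echo: dict

    def validate(self) -> None:
        """Conservation checks: every decomposition sums to its total."""
        if self.n_input_variants != self.n_markers + self.n_discarded:
            raise AssertionError("input != kept + discarded")
        if self.marker_accounting.total != self.n_markers:
            raise AssertionError("marker SNP/indel split does not sum to total")
        if sum(self.class_counts.values()) != self.n_markers:
            raise AssertionError("class counts do not sum to marker total")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["input_accounting"] = dataclasses.asdict(self.input_accounting)
        d["marker_accounting"] = dataclasses.asdict(self.marker_accounting)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        d = json.loads(text)
        d["input_accounting"] = VariantAccounting(**d["input_accounting"])
        d["marker_accounting"] = VariantAccounting(**d["marker_accounting"])
        return cls(**d)


def _accounting(records) -> VariantAccounting:
    n_snps = sum(1 for r in records if r.is_snp)
    return VariantAccounting(n_snps=n_snps, n_indels=len(records) - n_snps)


def run_pipeline(config: PipelineConfig, write_artifacts: bool = True) -> RunReport:
    """Execute the whole analysis and write artifacts under the out prefix:
    simulated VCF + truth table (when simulating), markers TSV summary,
    index track TSV, candidate-region BED, and the JSON report."""
    prefix = config.out_prefix
    outdir = os.path.dirname(prefix)
    if write_artifacts and outdir:
        os.makedirs(outdir, exist_ok=True)

    if config.simulation is not None:
        log.info("stage simulate: %d variants", config.simulation.n_variants)
        ds = simulate_dataset(config.simulation)
        records = ds.records
        morgans_per_bp = {
            c.name: c.genetic_length_morgans / c.length_bp for c in config.simulation.genome
        }
        pool_size = ds.realized_pool_size
        if write_artifacts:
            write_vcf(records, [config.wildtype_sample, config.mutant_sample,
                                config.pool_sample], f"{prefix}.sim.vcf",
                      genome=config.simulation.genome)
            write_truth_tsv(ds.truth, f"{prefix}.truth.tsv")
    else:
        log.info("stage read: %s", config.input_path)
        records = read_variant_table(config.input_path)
        morgans_per_bp = config.morgans_per_bp
        pool_size = config.pool_size

    log.info("stage filter: %d input variants", len(records))
    marker_set = select_markers(records, config.mutant_sample, config.wildtype_sample)
    log.info("stage filter: kept %d, discarded %d", len(marker_set), marker_set.n_discarded)
    summary = spectrum_summary(marker_set)

    log.info("stage scan: %d markers", len(marker_set))
    scan = genome_scan(
        marker_set,
        pool_sample=config.pool_sample,
        params=config.smoothing,
        q=config.quantile,
        n_sims=config.n_null_sims,
        pool_size=pool_size,
        morgans_per_bp=morgans_per_bp,
        seed=config.seed,
    )

    report = RunReport(
        version=__version__,
        seed=config.seed,
        n_input_variants=len(records),
        input_accounting=_accounting(records),
        n_markers=len(marker_set),
        n_discarded=marker_set.n_discarded,
        marker_accounting=VariantAccounting(marker_set.n_snps, marker_set.n_indels),
        class_counts=dict(marker_set.class_counts),
        transition_percent=summary.transition_percent,
        threshold=scan.threshold,
        regions=scan.report["regions"],
        summit=scan.report["summit"],
        config_echo=config.config_echo,
    )
    report.validate()

    if write_artifacts:
        with open(f"{prefix}.spectrum.tsv", "w") as fh:
            fh.write("class\tcount\tfraction\n")
            for c, n in summary.counts.items():
                fh.write(f"{c}\t{n}\t{summary.fractions[c]:.6g}\n")
            fh.write(f"transitions_percent\t\t{summary.transition_percent}\n")
        write_track_tsv(scan.track, f"{prefix}.track.tsv")
        write_regions_bed(scan.regions, f"{prefix}.regions.bed")
        with open(f"{prefix}.report.json", "w") as fh:
            fh.write(report.to_json() + "\n")
    return report
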