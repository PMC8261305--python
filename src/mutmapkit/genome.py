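"""Genome coordinate frame, EMS substitution spectrum, and simulation configuration.

The genome model is deliberately minimal: a set of named chromosomes with a
physical length (bp) and a genetic length (Morgans). Physical and genetic
coordinates are related by a constant rate within each chromosome, which is
all the downstream mapping statistics need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "Chromosome",
    "GenomeModel",
    "EmsSpectrum",
    "SimulationConfig",
    "default_genome",
    "default_spectrum",
    "default_config",
]

# Substitution classes tracked by the spectrum. EMS alkylates guanine, so
# G:C -> A:T transitions (seen as G>A or C>T depending on the reported strand)
# dominate the induced-variant spectrum.
CLASS_GA = "G>A"
CLASS_CT = "C>T"
CLASS_OTHER_SNP = "other_snp"
CLASS_INDEL = "indel"
SPECTRUM_CLASSES = (CLASS_GA, CLASS_CT, CLASS_OTHER_SNP, CLASS_INDEL)


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    genetic_length_morgans: float

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"chromosome {self.name}: length_bp must be >= 1")
        if self.genetic_length_morgans < 0:
            raise ValueError(f"chromosome {self.name}: genetic length must be >= 0")

    def bp_to_morgans(self, pos_bp) -> float:
        """Genetic position of a physical coordinate (constant cM/Mb)."""
        return pos_bp / self.length_bp * self.genetic_length_morgans


@dataclass(frozen=True)
class GenomeModel:
    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")

    def __iter__(self):
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def total_bp(self) -> int:
        return sum(c.length_bp for c in self.chromosomes)

    def get(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    def contains(self, chrom: str, pos_bp: int) -> bool:
        try:
            c = self.get(chrom)
        except KeyError:
            return False
        return 1 <= pos_bp <= c.length_bp


@dataclass(frozen=True)
class EmsSpectrum:
    """Probabilities of induced-variant classes (must sum to 1)."""

    probabilities: dict[str, float]

    def __post_init__(self) -> None:
        for k in self.probabilities:
            if k not in SPECTRUM_CLASSES:
                raise ValueError(f"unknown substitution class {k!r}")
        p = list(self.probabilities.values())
        if any(x < 0 for x in p):
            raise ValueError("spectrum probabilities must be >= 0")
        if abs(sum(p) - 1.0) > 1e-9:
            raise ValueError(f"spectrum probabilities sum to {sum(p)}, not 1")

    def as_arrays(self):
        classes = [c for c in SPECTRUM_CLASSES if c in self.probabilities]
        probs = [self.probabilities[c] for c in classes]
        return classes, probs

    @property
    def transition_fraction(self) -> float:
        return self.probabilities.get(CLASS_GA, 0.0) + self.probabilities.get(CLASS_CT, 0.0)


def default_genome() -> GenomeModel:
    """Ten-chromosome maize-like genome.

    Physical lengths approximate the B73 v4 assembly; genetic lengths are a
    modelling choice (~15 Morgans total, in line with consensus maize maps)
    since no map lengths are dictated by the mapping statistics themselves.
    """
    sizes_mb = [307, 244, 236, 247, 224, 174, 182, 181, 159, 151]
    morgans = [2.0, 1.7, 1.7, 1.6, 1.7, 1.2, 1.4, 1.4, 1.3, 1.2]
    return GenomeModel(
        tuple(
            Chromosome(f"chr{i + 1}", mb * 1_000_000, m)
            for i, (mb, m) in enumerate(zip(sizes_mb, morgans))
        )
    )


def default_spectrum() -> EmsSpectrum:
    """EMS spectrum matching observed induced-marker class counts
    2730 G>A, 2465 C>T, 169 other SNPs, 290 indels out of 5654."""
    n = 5654.0
    return EmsSpectrum(
        {
            CLASS_GA: 2730 / n,
            CLASS_CT: 2465 / n,
            CLASS_OTHER_SNP: 169 / n,
            CLASS_INDEL: 290 / n,
        }
    )


@dataclass
class SimulationConfig:
    """Parameters of one synthetic MutMap experiment.

    ``causal=None`` simulates the no-causal-locus null: the phenotype is
    independent of genotype and the "mutant bulk" is a random draw of F2
    individuals.
    """

    genome: GenomeModel = field(default_factory=default_genome)
    n_variants: int = 5654
    spectrum: EmsSpectrum = field(default_factory=default_spectrum)
    causal: Optional[tuple[str, int]] = ("chr4", 195_678_521)
    causal_in_markers: bool = True  # drop the causal site itself to test pure linkage
    n_f2: int = 1000
    pool_size: int = 200
    mean_depth_pool: float = 60.0
    mean_depth_wt: float = 15.0
    mean_depth_mut: float = 20.0
    sequencing_error_rate: float = 0.001
    phenotyping_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.n_variants > self.genome.total_bp:
            raise ValueError("n_variants exceeds genome capacity")
        if self.causal is not None and not self.genome.contains(*self.causal):
            raise ValueError(f"causal locus {self.causal} outside genome")
        if self.n_f2 < 1 or self.pool_size < 1:
            raise ValueError("n_f2 and pool_size must be >= 1")
        if not (0 <= self.sequencing_error_rate < 0.5):
            raise ValueError("sequencing_error_rate must be in [0, 0.5)")
        if not (0 <= self.phenotyping_error_rate < 1):
            raise ValueError("phenotyping_error_rate must be in [0, 1)")
        for d in (self.mean_depth_pool, self.mean_depth_wt, self.mean_depth_mut):
            if d <= 0:
                raise ValueError("mean depths must be > 0")


def default_config(**overrides) -> SimulationConfig:
    return SimulationConfig(**overrides)
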