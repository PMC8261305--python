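"""Synthetic EMS / F2 / pooled-sequencing data generator.

Simulates the downstream product of a MutMap experiment: a table of
mutant-unique homozygous variants with per-sample allele depths for the two
parents and a phenotype-selected F2 pool. The chain is

  EMS variant positions & classes  ->  F2 meiosis (Haldane, no interference)
  ->  recessive bulk selection      ->  Poisson/binomial pooled read depths.

All randomness flows from one seeded ``numpy.random.Generator`` in a fixed
order, so a configuration plus seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import (
    CLASS_CT,
    CLASS_GA,
    CLASS_INDEL,
    CLASS_OTHER_SNP,
    Chromosome,
    GenomeModel,
    SimulationConfig,
)
from .variants import VariantRecord

__all__ = [
    "MarkerTemplate",
    "Gamete",
    "draw_ems_variants",
    "simulate_gamete",
    "simulate_f2_population",
    "select_mutant_bulk",
    "sample_pool_reads",
    "simulate_dataset",
    "SimulatedDataset",
]

WT_SAMPLE = "WT_PARENT"
MUT_SAMPLE = "MUT_PARENT"
POOL_SAMPLE = "MP"

# Representative allele strings per class; the mapping statistics only read
# the class, never the bases themselves.
_CLASS_ALLELES = {
    CLASS_GA: ("G", "A"),
    CLASS_CT: ("C", "T"),
}
_OTHER_SNPS = [("A", "C"), ("A", "G"), ("A", "T"), ("T", "C"), ("T", "G"), ("G", "C")]
_INDELS = [("A", "AT"), ("CA", "C"), ("G", "GTT"), ("TGA", "T")]


@dataclass(frozen=True)
class MarkerTemplate:
    """A mutagen-induced site before any sequencing: position and class."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_class: str
    is_causal: bool


def _alleles_for_class(cls: str, rng: np.random.Generator) -> tuple[str, str]:
    if cls in _CLASS_ALLELES:
        return _CLASS_ALLELES[cls]
    if cls == CLASS_OTHER_SNP:
        return _OTHER_SNPS[rng.integers(len(_OTHER_SNPS))]
    if cls == CLASS_INDEL:
        return _INDELS[rng.integers(len(_INDELS))]
    raise ValueError(f"unknown class {cls!r}")


def draw_ems_variants(
    genome: GenomeModel,
    n_variants: int,
    spectrum,
    causal: tuple[str, int] | None,
    rng: np.random.Generator | int,
) -> list[MarkerTemplate]:
    """Place ``n_variants`` induced variants uniformly over the genome.

    Sites are multinomial across chromosomes proportional to physical length,
    uniform within a chromosome, unique per chromosome (collisions redrawn),
    and classed by the spectrum. If ``causal`` is given, one of the
    ``n_variants`` sites is pinned to that locus and flagged; it is always a
    G>A substitution (the canonical EMS lesion).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if n_variants > genome.total_bp:
        raise ValueError("n_variants exceeds total genome length")
    if causal is not None and not genome.contains(*causal):
        raise ValueError(f"causal locus {causal} outside genome")

    lengths = np.array([c.length_bp for c in genome], dtype=float)
    n_free = n_variants - (1 if causal is not None else 0)
    per_chrom = rng.multinomial(n_free, lengths / lengths.sum())

    out: list[MarkerTemplate] = []
    for chrom, n_c in zip(genome, per_chrom):
        reserved = {causal[1]} if causal is not None and causal[0] == chrom.name else set()
        if n_c + len(reserved) > chrom.length_bp:
            raise ValueError(f"too many variants for {chrom.name}")
        positions: set[int] = set()
        while len(positions) < n_c:
            draw = rng.integers(1, chrom.length_bp + 1, size=n_c - len(positions))
            positions.update(int(p) for p in draw if p not in reserved)
        classes_avail, probs = spectrum.as_arrays()
        cls_idx = rng.choice(len(classes_avail), size=n_c, p=probs)
        for pos, ci in zip(sorted(positions), cls_idx):
            cls = classes_avail[ci]
            ref, alt = _alleles_for_class(cls, rng)
            out.append(MarkerTemplate(chrom.name, pos, ref, alt, cls, False))
        if causal is not None and causal[0] == chrom.name:
            ref, alt = _CLASS_ALLELES[CLASS_GA]
            out.append(MarkerTemplate(chrom.name, causal[1], ref, alt, CLASS_GA, True))
    order = {c.name: i for i, c in enumerate(genome)}
    out.sort(key=lambda m: (order[m.chrom], m.pos))
    return out


@dataclass(frozen=True)
class Gamete:
    """One recombinant gamete on a single chromosome.

    ``start_origin`` is the parental origin (0 = wild type, 1 = mutant) at
    genetic position 0; ``crossovers`` are sorted crossover positions in
    Morgans. Origin flips at each crossover (Haldane: Poisson-many, uniform,
    no interference).
    """

    start_origin: int
    crossovers: np.ndarray

    def origin_at(self, positions_morgans) -> np.ndarray:
        pos = np.atleast_1d(np.asarray(positions_morgans, dtype=float))
        flips = np.searchsorted(self.crossovers, pos, side="right")
        return (self.start_origin + flips) % 2


def simulate_gamete(genetic_length_morgans: float, rng: np.random.Generator | int) -> Gamete:
    """Draw one gamete from a fully heterozygous F1 under the Haldane model."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if genetic_length_morgans < 0:
        raise ValueError("genetic length must be >= 0")
    n_co = rng.poisson(genetic_length_morgans)
    crossovers = np.sort(rng.uniform(0.0, genetic_length_morgans, size=n_co))
    return Gamete(start_origin=int(rng.integers(2)), crossovers=crossovers)


def _marker_positions_morgans(markers: list[MarkerTemplate], chrom: Chromosome) -> np.ndarray:
    return np.array([chrom.bp_to_morgans(m.pos) for m in markers], dtype=float)


def _sample_gamete_matrix(
    pos_morgans: np.ndarray, n_gametes: int, rng: np.random.Generator
) -> np.ndarray:
    """Parental-origin matrix (n_gametes, n_markers) at the marker positions.

    Uses the Markov-chain form of the Haldane model: the origin switches
    between adjacent markers with probability r = (1 - e^(-2d))/2, which is
    exactly the crossover point process evaluated at marker resolution.
    """
    n = pos_morgans.size
    start = rng.integers(2, size=(n_gametes, 1))
    if n == 1:
        return start.astype(np.int8)
    d = np.diff(pos_morgans)
    r = 0.5 * (1.0 - np.exp(-2.0 * d))
    switches = rng.random((n_gametes, n - 1)) < r
    flips = np.cumsum(switches, axis=1)
    origins = np.concatenate([start, (start + flips) % 2], axis=1)
    return origins.astype(np.int8)


def simulate_f2_population(
    config: SimulationConfig,
    markers: list[MarkerTemplate],
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Genotype matrix (n_f2, n_markers) with codes 0/1/2 = count of the
    mutant-parent allele. Each individual is the sum of two independent F1
    gametes; chromosomes segregate independently."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    geno = np.empty((config.n_f2, len(markers)), dtype=np.int8)
    col = 0
    for chrom in config.genome:
        chrom_markers = [m for m in markers if m.chrom == chrom.name]
        if not chrom_markers:
            continue
        pos_m = _marker_positions_morgans(chrom_markers, chrom)
        g1 = _sample_gamete_matrix(pos_m, config.n_f2, rng)
        g2 = _sample_gamete_matrix(pos_m, config.n_f2, rng)
        geno[:, col : col + len(chrom_markers)] = g1 + g2
        col += len(chrom_markers)
    if col != len(markers):
        raise ValueError("markers reference chromosomes absent from the genome")
    return geno


def select_mutant_bulk(
    genotypes: np.ndarray,
    causal_col: int | None,
    pool_size: int,
    phenotyping_error_rate: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Indices of the phenotype-selected bulk.

    With a causal column, recessive (code 2) individuals are drawn; each
    selected slot is independently mis-phenotyped with the given error rate
    and replaced by a uniformly drawn non-mutant individual. ``causal_col``
    None models a phenotype unlinked to any marker: a uniform random bulk.
    Returns min(pool_size, available) indices.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    n = genotypes.shape[0]
    if causal_col is None:
        k = min(pool_size, n)
        return np.sort(rng.choice(n, size=k, replace=False))
    mutant = np.flatnonzero(genotypes[:, causal_col] == 2)
    if mutant.size == 0:
        raise ValueError(
            "no recessive-phenotype individuals in the F2 population; "
            f"expected ~{genotypes.shape[0] // 4} — increase n_f2"
        )
    k = min(pool_size, mutant.size)
    chosen = rng.choice(mutant, size=k, replace=False)
    if phenotyping_error_rate > 0:
        non_mutant = np.flatnonzero(genotypes[:, causal_col] != 2)
        if non_mutant.size:
            err = rng.random(k) < phenotyping_error_rate
            chosen[err] = rng.choice(non_mutant, size=int(err.sum()), replace=True)
    return np.sort(chosen)


def sample_pool_reads(
    allele_freq: np.ndarray,
    mean_depth: float,
    error_rate: float,
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled sequencing of per-marker allele frequencies.

    Depth ~ Poisson(mean_depth); alternate reads ~ Binomial(depth, f') with
    f' = f(1-e) + (1-f)e (symmetric ref<->alt base-call error). Returns
    (ref_counts, alt_counts).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    f = np.asarray(allele_freq, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("allele frequencies must be in [0, 1]")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    depth = rng.poisson(mean_depth, size=f.shape)
    p = f * (1 - error_rate) + (1 - f) * error_rate
    alt = rng.binomial(depth, p)
    return depth - alt, alt


@dataclass
class SimulatedDataset:
    """Everything one synthetic experiment produced."""

    config: SimulationConfig
    records: list[VariantRecord]
    truth: list[dict]  # chrom, pos, class, is_causal, true_bulk_allele_freq
    bulk_indices: np.ndarray
    realized_pool_size: int

    @property
    def causal_record(self) -> VariantRecord | None:
        for r in self.records:
            if r.is_causal:
                return r
        return None


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: variants -> F2 -> bulk -> pooled reads.

    Emits one VariantRecord per induced site with AD depths for the wild-type
    parent (all reference), mutant parent (all alternate) and the pooled
    mutant bulk, plus a truth table carrying each site's true bulk allele
    frequency.
    """
    rng = np.random.default_rng(config.seed)
    markers = draw_ems_variants(
        config.genome, config.n_variants, config.spectrum, config.causal, rng
    )
    geno = simulate_f2_population(config, markers, rng)
    if config.causal is None:
        causal_col = None
    else:
        causal_col = next(
            i for i, m in enumerate(markers) if m.is_causal
        )
    bulk = select_mutant_bulk(
        geno, causal_col, config.pool_size, config.phenotyping_error_rate, rng
    )
    freq = geno[bulk].mean(axis=0) / 2.0

    e = config.sequencing_error_rate
    pool_ref, pool_alt = sample_pool_reads(freq, config.mean_depth_pool, e, rng)
    wt_ref, wt_alt = sample_pool_reads(
        np.zeros(len(markers)), config.mean_depth_wt, e, rng
    )
    mut_ref, mut_alt = sample_pool_reads(
        np.ones(len(markers)), config.mean_depth_mut, e, rng
    )

    records, truth = [], []
    for i, m in enumerate(markers):
        if m.is_causal and not config.causal_in_markers:
            continue
        records.append(
            VariantRecord(
                chrom=m.chrom,
                pos=m.pos,
                ref_allele=m.ref_allele,
                alt_allele=m.alt_allele,
                depths={
                    WT_SAMPLE: (int(wt_ref[i]), int(wt_alt[i])),
                    MUT_SAMPLE: (int(mut_ref[i]), int(mut_alt[i])),
                    POOL_SAMPLE: (int(pool_ref[i]), int(pool_alt[i])),
                },
                is_causal=m.is_causal,
            )
        )
        truth.append(
            {
                "chrom": m.chrom,
                "pos": m.pos,
                "class": m.variant_class,
                "is_causal": m.is_causal,
                "true_bulk_allele_freq": float(freq[i]),
            }
        )
    return SimulatedDataset(
        config=config,
        records=records,
        truth=truth,
        bulk_indices=bulk,
        realized_pool_size=int(bulk.size),
    )
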