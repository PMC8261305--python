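"""Read-count variant filtering and mutant-unique marker selection.

The rules operate on per-sample allele depths (AD) only:

* a site is *supported* when its total depth exceeds two reads;
* a sample is *homozygous* for an allele when that allele has at least four
  reads and the other allele at most one (one stray read is tolerated as
  sequencing error);
* a *marker* is a variant homozygous-alternate in the mutagenised parent and
  absent (at the same one-read tolerance) or homozygous-reference in the
  wild-type parent.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .genome import CLASS_CT, CLASS_GA, CLASS_INDEL, CLASS_OTHER_SNP

__all__ = [
    "Zygosity",
    "VariantRecord",
    "MarkerSet",
    "SpectrumSummary",
    "is_supported",
    "classify_zygosity",
    "is_wildtype_clean",
    "select_markers",
    "spectrum_summary",
    "variant_class",
]


class Zygosity(enum.Enum):
    HOM_ALT = "hom_alt"
    HOM_REF = "hom_ref"
    HET = "het"
    AMBIGUOUS = "ambiguous"


def variant_class(ref: str, alt: str) -> str:
    """Substitution class of an allele pair: 'G>A', 'C>T', other SNP, or indel."""
    if len(ref) == 1 and len(alt) == 1:
        sub = f"{ref.upper()}>{alt.upper()}"
        if sub == CLASS_GA:
            return CLASS_GA
        if sub == CLASS_CT:
            return CLASS_CT
        return CLASS_OTHER_SNP
    return CLASS_INDEL


@dataclass
class VariantRecord:
    """One biallelic called site with per-sample (ref, alt) read depths."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    depths: dict[str, tuple[int, int]]
    is_causal: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        for s, (r, a) in self.depths.items():
            if r < 0 or a < 0:
                raise ValueError(f"negative depth for sample {s}")

    @property
    def variant_class(self) -> str:
        return variant_class(self.ref_allele, self.alt_allele)

    @property
    def is_snp(self) -> bool:
        return self.variant_class != CLASS_INDEL

    def depth_of(self, sample: str) -> tuple[int, int]:
        try:
            return self.depths[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} not present at {self.chrom}:{self.pos}") from None


def is_supported(ref_count: int, alt_count: int) -> bool:
    """A site is a real variant only when covered by more than two reads."""
    return ref_count + alt_count > 2


def classify_zygosity(ref_count: int, alt_count: int) -> Zygosity:
    """Classify a sample's genotype from its allele read counts.

    HOM_ALT: alt >= 4 and ref <= 1 (mirrored for HOM_REF); HET: both alleles
    seen at least twice at a supported site; anything else is AMBIGUOUS
    (typically low depth).
    """
    if alt_count >= 4 and ref_count <= 1:
        return Zygosity.HOM_ALT
    if ref_count >= 4 and alt_count <= 1:
        return Zygosity.HOM_REF
    if ref_count >= 2 and alt_count >= 2 and is_supported(ref_count, alt_count):
        return Zygosity.HET
    return Zygosity.AMBIGUOUS


def is_wildtype_clean(ref_count: int, alt_count: int) -> bool:
    """True when the wild-type parent shows no credible alternate allele:
    homozygous reference, or at most one (tolerated) alternate read."""
    return classify_zygosity(ref_count, alt_count) is Zygosity.HOM_REF or alt_count <= 1


@dataclass
class MarkerSet:
    """Mutant-unique homozygous variants used as mapping markers."""

    markers: list[VariantRecord]
    n_input: int = 0
    n_discarded: int = 0
    class_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.class_counts:
            self.class_counts = _count_classes(self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    @property
    def n_snps(self) -> int:
        return sum(n for c, n in self.class_counts.items() if c != CLASS_INDEL)

    @property
    def n_indels(self) -> int:
        return self.class_counts.get(CLASS_INDEL, 0)


def _count_classes(records) -> dict[str, int]:
    counts = {CLASS_GA: 0, CLASS_CT: 0, CLASS_OTHER_SNP: 0, CLASS_INDEL: 0}
    for r in records:
        counts[r.variant_class] += 1
    return counts


def select_markers(
    records: list[VariantRecord],
    mutant_sample: str,
    wildtype_sample: str,
) -> MarkerSet:
    """Keep variants homozygous-alternate in the mutant parent and clean in
    the wild-type parent; the pool sample plays no role here."""
    kept = []
    for rec in records:
        mr, ma = rec.depth_of(mutant_sample)
        wr, wa = rec.depth_of(wildtype_sample)
        if classify_zygosity(mr, ma) is Zygosity.HOM_ALT and is_wildtype_clean(wr, wa):
            kept.append(rec)
    kept.sort(key=lambda r: (r.chrom, r.pos))
    return MarkerSet(markers=kept, n_input=len(records), n_discarded=len(records) - len(kept))


@dataclass(frozen=True)
class SpectrumSummary:
    counts: dict[str, int]
    fractions: dict[str, float]
    transition_percent: float  # (G>A + C>T) / all markers, in %, 1 decimal

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def spectrum_summary(markers) -> SpectrumSummary:
    """Per-class marker counts and the combined G>A + C>T transition share.

    The denominator is the full marker set, indels included. Accepts a
    MarkerSet, a list of records, or a precomputed {class: count} mapping.
    """
    if isinstance(markers, dict):
        counts = dict(markers)
    elif isinstance(markers, MarkerSet):
        counts = dict(markers.class_counts)
    else:
        counts = _count_classes(markers)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty marker set")
    fractions = {c: n / total for c, n in counts.items()}
    transitions = counts.get(CLASS_GA, 0) + counts.get(CLASS_CT, 0)
    return SpectrumSummary(
        counts=counts,
        fractions=fractions,
        transition_percent=round(100.0 * transitions / total, 1),
    )
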