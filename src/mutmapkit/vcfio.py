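"""Reading and writing variant tables: VCF 4.2 with per-sample AD, and a
plain TSV dialect carrying the same data model.

Coordinates are 1-based closed in VCF/TSV; exported BED intervals are
0-based half-open. Multi-allelic VCF records are split into biallelic
records on input (the AD reference count is shared between the splits).
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genome import GenomeModel
from .variants import VariantRecord

__all__ = [
    "write_vcf",
    "read_vcf",
    "read_variant_table",
    "write_variant_tsv",
    "read_variant_tsv",
    "write_track_tsv",
    "write_regions_bed",
    "write_truth_tsv",
]


def write_vcf(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    path: str,
    genome: GenomeModel | None = None,
) -> None:
    """Write biallelic records as uncompressed VCF 4.2 with FORMAT AD.

    Records must be free of duplicate (chrom, pos, alt) sites; contig header
    lines carry lengths when a genome model is supplied.
    """
    seen = set()
    for r in records:
        key = (r.chrom, r.pos, r.alt_allele)
        if key in seen:
            raise ValueError(f"duplicate record at {r.chrom}:{r.pos} {r.alt_allele}")
        seen.add(key)

    lines = ["##fileformat=VCFv4.2", "##source=mutmapkit"]
    if genome is not None:
        for c in genome:
            lines.append(f"##contig=<ID={c.name},length={c.length_bp}>")
    else:
        for chrom in dict.fromkeys(r.chrom for r in records):
            lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Allelic depths for the ref and alt alleles">'
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for r in records:
        ads = []
        for s in samples:
            ref_c, alt_c = r.depth_of(s)
            ads.append(f"{ref_c},{alt_c}")
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref_allele}\t{r.alt_allele}\t.\tPASS\t.\tAD\t"
            + "\t".join(ads)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path: str) -> list[VariantRecord]:
    """Read a VCF with per-sample AD into biallelic VariantRecords.

    Accepts both the Number=R dialect written by :func:`write_vcf` and
    GATK-style AD. Multi-allelic records are split per alternate allele.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    out: list[VariantRecord] = []
    for line_no, v in enumerate(vcf, start=1):
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise ValueError(f"missing AD field at record {line_no} ({v.CHROM}:{v.POS})")
        ad = np.asarray(ad)
        for alt_i, alt in enumerate(v.ALT):
            depths = {}
            for si, s in enumerate(samples):
                ref_c = int(ad[si, 0])
                alt_c = int(ad[si, alt_i + 1])
                if ref_c < 0 or alt_c < 0:  # htslib encodes missing as negative
                    ref_c, alt_c = max(ref_c, 0), max(alt_c, 0)
                depths[s] = (ref_c, alt_c)
            out.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref_allele=v.REF,
                    alt_allele=alt,
                    depths=depths,
                )
            )
    out.sort(key=lambda r: (r.chrom, r.pos, r.alt_allele))
    return out


_TSV_FIXED = ["chrom", "pos", "ref_allele", "alt_allele"]


def write_variant_tsv(records: Sequence[VariantRecord], samples: Sequence[str], path: str) -> None:
    """TSV dialect: fixed columns then '<sample>:ref'/'<sample>:alt' pairs."""
    cols = _TSV_FIXED + [f"{s}:{side}" for s in samples for side in ("ref", "alt")]
    rows = []
    for r in records:
        row = [r.chrom, r.pos, r.ref_allele, r.alt_allele]
        for s in samples:
            rc, ac = r.depth_of(s)
            row += [rc, ac]
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_variant_tsv(path: str) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TSV_FIXED if c not in df.columns]
    if missing:
        raise ValueError(f"variant TSV missing columns {missing}")
    samples = sorted({c.rsplit(":", 1)[0] for c in df.columns if c.endswith(":ref")})
    out = []
    for _, row in df.iterrows():
        depths = {s: (int(row[f"{s}:ref"]), int(row[f"{s}:alt"])) for s in samples}
        out.append(
            VariantRecord(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref_allele=str(row["ref_allele"]),
                alt_allele=str(row["alt_allele"]),
                depths=depths,
            )
        )
    out.sort(key=lambda r: (r.chrom, r.pos, r.alt_allele))
    return out


def read_variant_table(path: str) -> list[VariantRecord]:
    """Dispatch on extension: .vcf -> VCF reader, anything else -> TSV."""
    if path.endswith(".vcf") or path.endswith(".vcf.gz"):
        return read_vcf(path)
    return read_variant_tsv(path)


def write_track_tsv(track: pd.DataFrame, path: str) -> None:
    """Index track (1-based positions) for plotting a genome-scan panel."""
    track.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_regions_bed(regions: Iterable, path: str) -> None:
    """Candidate regions as BED (0-based half-open), summit in column 4."""
    with open(path, "w") as fh:
        fh.write("# candidate regions; BED 0-based half-open; name=summit_pos(1-based):summit_value\n")
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t"
                f"{r.summit_pos}:{r.summit_value:.4f}\n"
            )


def write_truth_tsv(truth: list[dict], path: str) -> None:
    pd.DataFrame(truth).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_truth_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
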