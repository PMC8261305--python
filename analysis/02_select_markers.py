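"""Select mutant-unique homozygous markers and summarise their spectrum.

Applies the read-count rules (support >2 reads; homozygous = one allele >=4
reads, the other <=1; marker = homozygous-alternate in the mutant parent and
clean in the wild type) to the simulated VCF and reports the SNP/indel
accounting and the G>A + C>T transition percentage.
"""

import pathlib

from mutmapkit import select_markers, spectrum_summary
from mutmapkit.simulate import MUT_SAMPLE, POOL_SAMPLE, WT_SAMPLE
from mutmapkit.vcfio import read_vcf, write_vcf

RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    vcf = RESULTS / "sim.vcf"
    if not vcf.exists():
        raise SystemExit("run analysis/01_simulate_experiment.py first")
    records = read_vcf(str(vcf))
    markers = select_markers(records, MUT_SAMPLE, WT_SAMPLE)
    summary = spectrum_summary(markers)
    write_vcf(list(markers), [WT_SAMPLE, MUT_SAMPLE, POOL_SAMPLE],
              str(RESULTS / "markers.vcf"))
    with open(RESULTS / "spectrum.tsv", "w") as fh:
        fh.write("class\tcount\tfraction\n")
        for c, n in summary.counts.items():
            fh.write(f"{c}\t{n}\t{summary.fractions[c]:.6g}\n")
    print(f"kept {len(markers)} of {markers.n_input} variants as markers "
          f"({markers.n_snps} SNPs + {markers.n_indels} indels)")
    print(f"transition (G>A + C>T) share: {summary.transition_percent}%")
    print(f"wrote {RESULTS/'markers.vcf'} and {RESULTS/'spectrum.tsv'}")


if __name__ == "__main__":
    main()
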