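#!/usr/bin/env python
"""Descriptive SNP summaries of the simulated pools.

Computes, per pool, the 10-bin minor-allele-frequency spectrum and the
homozygous (alt-fixed) / heterozygous (segregating) SNP classification,
writing both tables under results/summaries/ and printing the headline
proportions.
"""

from pathlib import Path

from poolscan import het_hom_counts, maf_spectrum, read_count_table
from poolscan.snp_summaries import write_maf_spectrum

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "summaries"
    out.mkdir(parents=True, exist_ok=True)
    table = read_count_table(ROOT / "sim" / "counts.tsv")
    spectra = [maf_spectrum(table, p) for p in table.pool_names]
    write_maf_spectrum(out / "maf_spectrum.tsv", spectra)
    with open(out / "het_hom.tsv", "w") as fh:
        fh.write("pool\tn_snps\thomozygous\theterozygous\tpct_heterozygous\n")
        for p in table.pool_names:
            hom, het = het_hom_counts(table, p)
            pct = 100.0 * het / (hom + het)
            fh.write(f"{p}\t{table.n_snps}\t{hom}\t{het}\t{pct:.2f}\n")
            print(f"{p}: {het} heterozygous / {hom} alt-fixed SNPs "
                  f"({pct:.1f}% heterozygous)")
    top = max(range(10), key=lambda k: spectra[0].counts[k])
    print(f"\npool1 modal MAF class: [{top * 0.05:.2f}, {(top + 1) * 0.05:.2f}) "
          f"with {spectra[0].counts[top]} of {spectra[0].total} SNPs")
    print(f"tables -> {out}")


if __name__ == "__main__":
    main()
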