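"""SNP-level filters and descriptive summaries.

Covers the bookkeeping side of a pool-seq study: a count-level quality
filter (minimum alternate-read support, minimum per-pool depth, optional
rare-allele floor), the 10-bin minor-allele-frequency spectrum, and the
per-pool homozygous/heterozygous SNP classification — all computed from
read frequencies, since pools carry no individual genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import SnpTable

N_MAF_BINS = 10
MAF_BIN_WIDTH = 0.05


@dataclass
class MafSpectrum:
    """Counts of SNPs per MAF class [0,0.05), [0.05,0.10), …, [0.45,0.50]."""

    pool: str
    counts: np.ndarray
    total: int

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.total if self.total else self.counts.astype(float)

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(N_MAF_BINS + 1) * MAF_BIN_WIDTH


def filter_snps(
    snps: SnpTable,
    min_alt_reads: int = 3,
    min_depth: int = 4,
    maf_floor: float = 0.0,
) -> SnpTable:
    """Count-level SNP filter; idempotent.

    Per pool, count contributions with total depth < ``min_depth`` are
    zeroed (that pool's evidence is too thin to use, but other pools keep
    the site).  A SNP is retained only if, after that, at least one pool
    still shows ``min_alt_reads`` alternate reads — an approximation of
    read-level support filters (distinct alignment start sites cannot be
    checked from counts).  Optionally, SNPs whose pooled (across-pools)
    minor-allele frequency falls below ``maf_floor`` are dropped, the way
    rare alleles are typically removed during variant calling.
    """
    depth = snps.depths
    thin = depth < min_depth
    ref_c = np.where(thin, 0, snps.ref_counts)
    alt_c = np.where(thin, 0, snps.alt_counts)
    keep = (alt_c >= min_alt_reads).any(axis=1)
    if maf_floor > 0:
        tot_alt = alt_c.sum(axis=1)
        tot = ref_c.sum(axis=1) + tot_alt
        with np.errstate(invalid="ignore"):
            f = np.where(tot > 0, tot_alt / np.maximum(tot, 1), 0.0)
        pooled_maf = np.minimum(f, 1.0 - f)
        keep &= pooled_maf >= maf_floor
    return snps.with_counts(ref_c, alt_c).take(np.flatnonzero(keep))


def maf_spectrum(snps: SnpTable, pool: str) -> MafSpectrum:
    """10-bin MAF histogram for one pool.

    MAF = min_count/(maj_count+min_count) per SNP; bins are left-closed
    with the top bin [0.45, 0.50] closed at 0.5; zero-depth SNPs are
    skipped.
    """
    j = snps.pool_index(pool)
    depth = snps.depths[:, j]
    nz = depth > 0
    # integer arithmetic keeps bin boundaries exact: bin k iff MAF in [k/20, (k+1)/20)
    bins = np.minimum(
        (N_MAF_BINS * 2 * snps.min_counts[nz, j]) // depth[nz], N_MAF_BINS - 1
    )
    counts = np.bincount(bins, minlength=N_MAF_BINS)
    return MafSpectrum(pool=pool, counts=counts, total=int(nz.sum()))


def het_hom_counts(snps: SnpTable, pool: str) -> tuple[int, int]:
    """(homozygous, heterozygous) SNP counts for one pool.

    Among nonzero-depth SNPs: homozygous means fixed for the alternate
    allele (alt frequency 1); heterozygous means segregating (0 < alt
    frequency < 1); sites fixed for the reference are not variants in the
    pool and count in neither class.
    """
    j = snps.pool_index(pool)
    depth = snps.depths[:, j]
    nz = depth > 0
    alt = snps.alt_counts[nz, j]
    hom = int((alt == depth[nz]).sum())
    het = int(((alt > 0) & (alt < depth[nz])).sum())
    return hom, het


def write_maf_spectrum(path, spectra: list[MafSpectrum]) -> None:
    """Spectrum TSV: pool, bin_low, bin_high, count, fraction."""
    with open(path, "w") as fh:
        fh.write("pool\tbin_low\tbin_high\tcount\tfraction\n")
        for sp in spectra:
            edges = sp.bin_edges
            for k in range(N_MAF_BINS):
                frac = sp.fractions[k]
                fh.write(
                    f"{sp.pool}\t{edges[k]:.2f}\t{edges[k + 1]:.2f}\t"
                    f"{int(sp.counts[k])}\t{frac:.6f}\n"
                )
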