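"""Candidate-locus calling from window scores.

The scan flags windows under two criteria — extremely low ZHp (deficit of
pooled heterozygosity, default ZHp ≤ −4) and extremely high di (top 1% of
the di distribution) — merges flagged windows into loci, intersects the
two locus sets (the overlap being the highest-confidence candidates),
annotates loci with overlapping genes, and separately calls
breed-specific SNPs inside gene bodies plus flanking sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import IntervalSet, SnpTable
from .sweep_stats import WindowScores

DEFAULT_ZHP_THRESHOLD = -4.0
DEFAULT_DI_QUANTILE = 0.99
DEFAULT_FLANK = 1_000


@dataclass
class SelectionFlags:
    """Per-window boolean flags for one focal pool, plus realized cutoffs."""

    focal: str
    low_zhp: np.ndarray
    high_di: np.ndarray
    zhp_threshold: float
    di_quantile: float
    di_cutoff: float


@dataclass
class CandidateLocus:
    """A merged run of flagged windows (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    criterion: str  # "low_zhp" | "high_di" | "both"
    min_zhp: float = float("nan")
    max_di: float = float("nan")
    n_windows: int = 0
    genes: list[str] = field(default_factory=list)


def select_windows(
    scores: WindowScores,
    focal: str,
    zhp_threshold: float = DEFAULT_ZHP_THRESHOLD,
    di_quantile: float = DEFAULT_DI_QUANTILE,
) -> SelectionFlags:
    """Flag windows with ZHp ≤ threshold or di at/above the top quantile.

    The di cutoff is the ``di_quantile`` quantile (linear interpolation
    between order statistics) of defined di values; windows tied exactly
    at the cutoff are flagged.  The realized cutoff is returned so other
    quantile conventions can be audited.
    """
    j = scores.pool_names.index(focal)
    zhp = scores.zhp[:, j]
    di = scores.di[focal]
    if np.isnan(zhp).all() and np.isnan(di).all():
        raise ValueError(f"no windows with defined scores for pool {focal!r}")
    with np.errstate(invalid="ignore"):
        low_zhp = ~np.isnan(zhp) & (zhp <= zhp_threshold)
    defined_di = di[~np.isnan(di)]
    if len(defined_di) == 0:
        raise ValueError(f"no windows with defined di for pool {focal!r}")
    cutoff = float(np.quantile(defined_di, di_quantile))
    with np.errstate(invalid="ignore"):
        high_di = ~np.isnan(di) & (di >= cutoff)
    return SelectionFlags(
        focal=focal,
        low_zhp=low_zhp,
        high_di=high_di,
        zhp_threshold=zhp_threshold,
        di_quantile=di_quantile,
        di_cutoff=cutoff,
    )


def merge_windows(
    scores: WindowScores,
    flags: np.ndarray,
    focal: str,
    criterion: str,
) -> list[CandidateLocus]:
    """Merge overlapping or book-ended flagged windows into loci.

    Windows merge when they overlap or abut (gap ≤ 0 bp) on the same
    chromosome; min ZHp / max di are aggregated over member windows.
    """
    frame = scores.frame
    j = scores.pool_names.index(focal)
    zhp = scores.zhp[:, j]
    di = scores.di.get(focal)
    order = np.lexsort((frame.start, frame.chrom))
    loci: list[CandidateLocus] = []
    for w in order:
        if not flags[w]:
            continue
        c, s, e = str(frame.chrom[w]), int(frame.start[w]), int(frame.end[w])
        z = float(zhp[w]) if not np.isnan(zhp[w]) else float("nan")
        d = float(di[w]) if di is not None and not np.isnan(di[w]) else float("nan")
        if loci and loci[-1].chrom == c and s <= loci[-1].end:
            cur = loci[-1]
            cur.end = max(cur.end, e)
            cur.min_zhp = np.nanmin([cur.min_zhp, z])
            cur.max_di = np.nanmax([cur.max_di, d])
            cur.n_windows += 1
        else:
            loci.append(
                CandidateLocus(
                    chrom=c, start=s, end=e, criterion=criterion,
                    min_zhp=z, max_di=d, n_windows=1,
                )
            )
    return loci


def intersect_loci(
    low_zhp_loci: list[CandidateLocus], high_di_loci: list[CandidateLocus]
) -> list[CandidateLocus]:
    """Pairwise intersections (≥1 bp) of the two locus sets.

    Intersections carry min ZHp from the low-ZHp side and max di from the
    high-di side and are labelled criterion ``both``.
    """
    out: list[CandidateLocus] = []
    for a in low_zhp_loci:
        for b in high_di_loci:
            if a.chrom != b.chrom:
                continue
            s, e = max(a.start, b.start), min(a.end, b.end)
            if s < e:
                out.append(
                    CandidateLocus(
                        chrom=a.chrom, start=s, end=e, criterion="both",
                        min_zhp=a.min_zhp, max_di=b.max_di,
                        n_windows=min(a.n_windows, b.n_windows),
                    )
                )
    out.sort(key=lambda l: (l.chrom, l.start, l.end))
    return out


def annotate_loci(
    loci: list[CandidateLocus], genes: IntervalSet
) -> list[CandidateLocus]:
    """Attach every gene whose interval overlaps a locus by ≥1 bp.

    Intervals are half-open, so a gene abutting the locus end is not
    attached.  Annotation is in place; the list is returned for chaining.
    """
    for locus in loci:
        on = genes.chrom == locus.chrom
        hit = on & (genes.start < locus.end) & (genes.end > locus.start)
        locus.genes = [str(n) for n in genes.name[hit]]
    return loci


def breed_specific_snps(
    snps: SnpTable,
    focal: str,
    gene_intervals: IntervalSet,
    flank: int = DEFAULT_FLANK,
    conserved: IntervalSet | None = None,
    min_alt_freq: float = 0.5,
) -> np.ndarray:
    """Indices of SNPs private to the focal pool near genes.

    A SNP qualifies when (a) the focal pool's major allele is the
    alternate (alt read frequency > ``min_alt_freq``), (b) every other
    pool's major allele is the reference (alt frequency < 1 − that bound;
    zero-depth pools cannot vouch and disqualify the site), (c) the
    position lies within a gene interval extended by ``flank`` bp on both
    sides, and (d) when ``conserved`` is given, the position also lies in
    a conserved interval.
    """
    if snps.n_pools < 2:
        raise ValueError("breed-specific SNP calling needs at least 2 pools")
    j = snps.pool_index(focal)
    freqs = snps.alt_freqs()
    with np.errstate(invalid="ignore"):
        focal_alt_major = ~np.isnan(freqs[:, j]) & (freqs[:, j] > min_alt_freq)
        others = [k for k in range(snps.n_pools) if k != j]
        others_ref_major = np.ones(snps.n_snps, dtype=bool)
        for k in others:
            others_ref_major &= ~np.isnan(freqs[:, k]) & (
                freqs[:, k] < 1.0 - min_alt_freq
            )
    pos0 = snps.pos - 1
    in_genes = gene_intervals.pad(flank).contains(snps.chrom, pos0)
    keep = focal_alt_major & others_ref_major & in_genes
    if conserved is not None:
        keep &= conserved.contains(snps.chrom, pos0)
    return np.flatnonzero(keep)


def loci_to_intervals(loci: list[CandidateLocus]) -> IntervalSet:
    """Loci as a BED-compatible IntervalSet (name = comma-joined genes)."""
    if not loci:
        return IntervalSet.empty()
    return IntervalSet(
        np.array([l.chrom for l in loci], dtype=object),
        np.array([l.start for l in loci], dtype=np.int64),
        np.array([l.end for l in loci], dtype=np.int64),
        np.array([",".join(l.genes) if l.genes else "." for l in loci], dtype=object),
    )


def write_loci_tsv(path, loci: list[CandidateLocus]) -> None:
    """Locus table: chrom, start, end, criterion, min_zhp, max_di, n_windows, genes."""
    def fmt(x: float) -> str:
        return "NA" if np.isnan(x) else f"{x:.6f}"

    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcriterion\tmin_zhp\tmax_di\tn_windows\tgenes\n")
        for l in sorted(loci, key=lambda l: (l.chrom, l.start, l.end, l.criterion)):
            genes = ",".join(l.genes) if l.genes else "."
            fh.write(
                f"{l.chrom}\t{l.start}\t{l.end}\t{l.criterion}\t"
                f"{fmt(l.min_zhp)}\t{fmt(l.max_di)}\t{l.n_windows}\t{genes}\n"
            )


def write_loci_bed(path, loci: list[CandidateLocus]) -> None:
    """BED6-like locus output: name = genes, score = max di (0 if absent)."""
    with open(path, "w") as fh:
        for l in sorted(loci, key=lambda l: (l.chrom, l.start, l.end, l.criterion)):
            genes = ",".join(l.genes) if l.genes else "."
            score = 0.0 if np.isnan(l.max_di) else l.max_di
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{genes}\t{score:.6f}\t.\n")
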