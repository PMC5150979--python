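"""Readers and writers for pooled SNP data and genomic intervals.

Pool-seq experiments yield per-site read counts for each population pool
rather than individual genotypes.  The central container here,
:class:`SnpTable`, therefore stores reference/alternate *read counts* per
pool; the per-pool major/minor orientation needed by the heterozygosity
statistic is derived on demand.

Coordinate conventions: positions are stored 1-based as in VCF; all BED
and TSV interval output is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .sweep_stats import WindowScores

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


@dataclass
class SnpTable:
    """Biallelic SNPs with per-pool reference/alternate read counts.

    Arrays are parallel over SNP records, sorted by (chrom, pos) with
    positions 1-based.  ``ref_counts``/``alt_counts`` have shape
    ``(n_snps, n_pools)`` with columns ordered as ``pool_names``.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    ref_counts: np.ndarray
    alt_counts: np.ndarray
    pool_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.ref_counts = np.atleast_2d(np.asarray(self.ref_counts, dtype=np.int64))
        self.alt_counts = np.atleast_2d(np.asarray(self.alt_counts, dtype=np.int64))
        self.validate()

    # -- derived views -------------------------------------------------

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    @property
    def n_pools(self) -> int:
        return len(self.pool_names)

    @property
    def maj_counts(self) -> np.ndarray:
        """Per SNP per pool, reads of the more frequently observed allele."""
        return np.maximum(self.ref_counts, self.alt_counts)

    @property
    def min_counts(self) -> np.ndarray:
        """Per SNP per pool, reads of the less frequently observed allele."""
        return np.minimum(self.ref_counts, self.alt_counts)

    @property
    def depths(self) -> np.ndarray:
        return self.ref_counts + self.alt_counts

    def alt_freqs(self) -> np.ndarray:
        """Per-pool alternate-allele read frequency; NaN at zero depth."""
        d = self.depths
        with np.errstate(invalid="ignore"):
            return np.where(d > 0, self.alt_counts / np.maximum(d, 1), np.nan)

    def pool_index(self, pool: str) -> int:
        try:
            return self.pool_names.index(pool)
        except ValueError:
            raise KeyError(
                f"pool {pool!r} not in table; available: {self.pool_names}"
            ) from None

    def take(self, indices: np.ndarray) -> "SnpTable":
        """Subset records (order-preserving)."""
        idx = np.asarray(indices)
        return SnpTable(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            ref_counts=self.ref_counts[idx],
            alt_counts=self.alt_counts[idx],
            pool_names=list(self.pool_names),
        )

    def with_counts(self, ref_counts: np.ndarray, alt_counts: np.ndarray) -> "SnpTable":
        return replace(self, ref_counts=ref_counts, alt_counts=alt_counts)

    def validate(self) -> None:
        n = self.n_snps
        if self.ref_counts.shape != (n, self.n_pools) or self.alt_counts.shape != (
            n,
            self.n_pools,
        ):
            raise ValueError(
                f"count arrays must be (n_snps, n_pools) = ({n}, {self.n_pools})"
            )
        if n == 0:
            return
        if (self.ref_counts < 0).any() or (self.alt_counts < 0).any():
            raise ValueError("negative read counts")
        for r, a in zip(self.ref, self.alt):
            if r not in _BASES or a not in _BASES or r == a:
                raise ValueError(f"not a biallelic SNP: ref={r!r} alt={a!r}")
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(n)):
            raise ValueError("records not sorted by (chrom, pos)")
        same = (self.chrom[1:] == self.chrom[:-1]) & (self.pos[1:] == self.pos[:-1])
        if same.any():
            i = int(np.flatnonzero(same)[0])
            raise ValueError(f"duplicate record at {self.chrom[i]}:{self.pos[i + 1]}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnpTable):
            return NotImplemented
        return (
            self.pool_names == other.pool_names
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.ref_counts, other.ref_counts)
            and np.array_equal(self.alt_counts, other.alt_counts)
        )


def _sort_snp_arrays(chrom, pos, *arrays):
    order = np.lexsort((pos, chrom))
    return (chrom[order], pos[order], *[a[order] for a in arrays])


@dataclass
class IntervalSet:
    """Genomic intervals, 0-based half-open, sorted by (chrom, start, end)."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    name: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.name = np.asarray(self.name, dtype=object)
        if (self.start >= self.end).any():
            i = int(np.flatnonzero(self.start >= self.end)[0])
            raise ValueError(
                f"empty interval {self.chrom[i]}:{self.start[i]}-{self.end[i]}"
            )
        order = np.lexsort((self.end, self.start, self.chrom))
        self.chrom = self.chrom[order]
        self.start = self.start[order]
        self.end = self.end[order]
        self.name = self.name[order]

    def __len__(self) -> int:
        return len(self.start)

    @classmethod
    def empty(cls) -> "IntervalSet":
        z: list = []
        return cls(np.array(z, dtype=object), np.array(z, dtype=np.int64),
                   np.array(z, dtype=np.int64), np.array(z, dtype=object))

    def pad(self, flank: int) -> "IntervalSet":
        """Extend each interval by ``flank`` bp on both sides (floored at 0)."""
        return IntervalSet(self.chrom.copy(), np.maximum(self.start - flank, 0),
                           self.end + flank, self.name.copy())

    def merged(self) -> "IntervalSet":
        """Union of intervals per chromosome (overlapping or book-ended)."""
        out_c, out_s, out_e, out_n = [], [], [], []
        for c, s, e in zip(self.chrom, self.start, self.end):
            if out_c and out_c[-1] == c and s <= out_e[-1]:
                out_e[-1] = max(out_e[-1], int(e))
            else:
                out_c.append(c)
                out_s.append(int(s))
                out_e.append(int(e))
        out_n = [f"{c}:{s}-{e}" for c, s, e in zip(out_c, out_s, out_e)]
        return IntervalSet(np.array(out_c, dtype=object),
                           np.array(out_s, dtype=np.int64),
                           np.array(out_e, dtype=np.int64),
                           np.array(out_n, dtype=object))

    def contains(self, chrom: np.ndarray, pos0: np.ndarray) -> np.ndarray:
        """Boolean membership of 0-based positions in the interval union."""
        m = self.merged()
        out = np.zeros(len(pos0), dtype=bool)
        for c in np.unique(np.asarray(chrom, dtype=object)):
            sel = np.asarray(chrom, dtype=object) == c
            on = m.chrom == c
            if not on.any():
                continue
            starts, ends = m.start[on], m.end[on]
            idx = np.searchsorted(starts, pos0[sel], side="right") - 1
            hit = (idx >= 0) & (pos0[sel] < ends[np.maximum(idx, 0)])
            out[sel] = hit
        return out


# ---------------------------------------------------------------------
# count-table TSV
# ---------------------------------------------------------------------

def read_count_table(path) -> SnpTable:
    """Read the tab-separated allele-count dialect.

    Header: ``chrom pos ref alt <pool>_ref <pool>_alt ...``.  Unsorted
    input is sorted on load (with a logged notice); non-integer or
    negative counts raise with the offending line number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    fixed = ["chrom", "pos", "ref", "alt"]
    if list(df.columns[:4]) != fixed:
        raise ValueError(f"count table must start with columns {fixed}")
    count_cols = list(df.columns[4:])
    pools: list[str] = []
    for col in count_cols:
        if col.endswith("_ref"):
            pools.append(col[:-4])
    for p in pools:
        for suffix in ("_ref", "_alt"):
            if f"{p}{suffix}" not in count_cols:
                raise ValueError(f"missing column {p}{suffix}")
    for col in ["pos", *count_cols]:
        vals = df[col]
        if not pd.api.types.is_integer_dtype(vals):
            bad = pd.to_numeric(vals, errors="coerce")
            nonint = bad.isna() | (bad != bad.round())
            line = int(nonint.idxmax()) + 2 if nonint.any() else 2
            raise ValueError(f"non-integer value in column {col} at line {line}")
        if (vals < 0).any():
            line = int((vals < 0).idxmax()) + 2
            raise ValueError(f"negative count at line {line}")
    chrom = df["chrom"].to_numpy(dtype=object)
    pos = df["pos"].to_numpy(dtype=np.int64)
    order = np.lexsort((pos, chrom))
    if not np.array_equal(order, np.arange(len(df))):
        logger.info("count table %s not sorted; sorting on load", path)
        df = df.iloc[order].reset_index(drop=True)
        chrom, pos = chrom[order], pos[order]
    ref_counts = df[[f"{p}_ref" for p in pools]].to_numpy(dtype=np.int64)
    alt_counts = df[[f"{p}_alt" for p in pools]].to_numpy(dtype=np.int64)
    return SnpTable(
        chrom=chrom,
        pos=pos,
        ref=df["ref"].to_numpy(dtype=object),
        alt=df["alt"].to_numpy(dtype=object),
        ref_counts=ref_counts,
        alt_counts=alt_counts,
        pool_names=pools,
    )


def write_count_table(path, table: SnpTable) -> None:
    """Write a SnpTable in the TSV dialect read by :func:`read_count_table`."""
    cols: dict = {
        "chrom": table.chrom,
        "pos": table.pos,
        "ref": table.ref,
        "alt": table.alt,
    }
    for j, p in enumerate(table.pool_names):
        cols[f"{p}_ref"] = table.ref_counts[:, j]
        cols[f"{p}_alt"] = table.alt_counts[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------

def read_pool_vcf(path, pool_names: Sequence[str]) -> tuple[SnpTable, dict[str, int]]:
    """Read per-pool allele depths from a multi-sample VCF.

    Each VCF sample is one pool; per-allele read depths are taken from the
    AD FORMAT field (genotype calls are ignored — pools have none).  Only
    biallelic SNPs are kept; indels, multiallelic records and records
    without AD are dropped and tallied in the returned summary.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    available = list(vcf.samples)
    missing = [p for p in pool_names if p not in available]
    if missing:
        raise KeyError(
            f"sample(s) {missing} not in VCF; available samples: {available}"
        )
    cols = [available.index(p) for p in pool_names]
    dropped = {"indel": 0, "multiallelic": 0, "no_ad": 0, "non_acgt": 0}
    chrom, pos, ref, alt, refc, altc = [], [], [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            dropped["multiallelic"] += 1
            continue
        if v.is_indel or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            dropped["indel"] += 1
            continue
        if v.REF not in _BASES or v.ALT[0] not in _BASES:
            dropped["non_acgt"] += 1
            continue
        ad = v.format("AD")
        if ad is None or ad.shape[1] < 2:
            dropped["no_ad"] += 1
            continue
        ad = np.maximum(ad[:, :2], 0)  # cyvcf2 encodes missing as negative
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        refc.append(ad[cols, 0])
        altc.append(ad[cols, 1])
    n = len(pos)
    table = SnpTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        ref_counts=np.array(refc, dtype=np.int64).reshape(n, len(pool_names)),
        alt_counts=np.array(altc, dtype=np.int64).reshape(n, len(pool_names)),
        pool_names=list(pool_names),
    )
    return table, {k: v for k, v in dropped.items() if v}


# ---------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------

def read_intervals_bed(path) -> IntervalSet:
    """Read a BED3/BED4 file (0-based half-open); 4th column is the name."""
    chrom, start, end, name = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: fewer than 3 BED columns")
            c, s, e = parts[0], int(parts[1]), int(parts[2])
            if s >= e:
                raise ValueError(f"line {lineno}: start {s} >= end {e}")
            chrom.append(c)
            start.append(s)
            end.append(e)
            name.append(parts[3] if len(parts) > 3 and parts[3] else f"{c}:{s}-{e}")
    return IntervalSet(
        np.array(chrom, dtype=object),
        np.array(start, dtype=np.int64),
        np.array(end, dtype=np.int64),
        np.array(name, dtype=object),
    )


def write_intervals_bed(path, intervals: IntervalSet) -> None:
    with open(path, "w") as fh:
        for c, s, e, n in zip(
            intervals.chrom, intervals.start, intervals.end, intervals.name
        ):
            fh.write(f"{c}\t{s}\t{e}\t{n}\n")


# ---------------------------------------------------------------------
# window scores
# ---------------------------------------------------------------------

def _fmt(x: float) -> str:
    return "NA" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.6f}"


def write_window_scores(path, scores: "WindowScores") -> None:
    """Write per-(window, pool) scores as a BED-like TSV.

    One row per window and pool: chrom, start, end, pop, n_snps, sum_nmaj,
    sum_nmin, hp, zhp, di.  Missing scores (excluded or undefined windows,
    non-focal di) are written as ``NA``.  Row order is (chrom, start, pop);
    floats use 6 decimals, so reruns are byte-identical.
    """
    frame = scores.frame
    order = np.lexsort((frame.start, frame.chrom))
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tpop\tn_snps\tsum_nmaj\tsum_nmin\thp\tzhp\tdi\n"
        )
        for w in order:
            for j, p in enumerate(sorted(scores.pool_names)):
                k = scores.pool_names.index(p)
                di = scores.di.get(p)
                fh.write(
                    "\t".join(
                        [
                            str(frame.chrom[w]),
                            str(frame.start[w]),
                            str(frame.end[w]),
                            p,
                            str(int(frame.n_snps[w])),
                            str(int(scores.sum_nmaj[w, k])),
                            str(int(scores.sum_nmin[w, k])),
                            _fmt(scores.hp[w, k]),
                            _fmt(scores.zhp[w, k]),
                            _fmt(di[w]) if di is not None else "NA",
                        ]
                    )
                    + "\n"
                )


def read_chrom_lengths(path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: need chrom<TAB>length")
            out[parts[0]] = int(parts[1])
    return out
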