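#!/usr/bin/env python
"""Run the dual-criterion selection scan and compare calls with the truth.

Reads the simulated counts from 01, filters SNPs, scores 150-kb windows
(step 75 kb) for pooled heterozygosity (Hp -> ZHp) and differentiation
(pairwise FST -> di for pool1), flags windows with ZHp <= -4 or di in
the top 1%, merges them into loci, and writes window scores and locus
tables under results/scan/.

It also reports how the planted-sweep dose shapes the scan: with 10% of
the genome swept, the sweeps themselves inflate the genome-wide sigma of
Hp, so no window reaches ZHp <= -4 and only the di criterion fires; a
second run with a single planted sweep (0.5% of windows) shows the same
pipeline calling the sweep under both criteria.
"""

from pathlib import Path

import numpy as np

from poolscan import (
    SimConfig,
    assign_snps,
    filter_snps,
    intersect_loci,
    make_windows,
    merge_windows,
    read_count_table,
    score_windows,
    select_windows,
    simulate_genome,
    write_window_scores,
)
from poolscan.io_formats import read_chrom_lengths, read_intervals_bed
from poolscan.locus_scan import write_loci_tsv
from poolscan.simulate import Sweep

ROOT = Path(__file__).resolve().parent.parent / "results"
FOCAL = "pool1"


def scan(table, chrom_lengths, truth_intervals, outdir, label):
    outdir.mkdir(parents=True, exist_ok=True)
    table = filter_snps(table)
    frame = assign_snps(table, make_windows(chrom_lengths, sorted(chrom_lengths)))
    scores = score_windows(table, frame, focal_pools=[FOCAL])
    flags = select_windows(scores, FOCAL)
    zhp_loci = merge_windows(scores, flags.low_zhp, FOCAL, "low_zhp")
    di_loci = merge_windows(scores, flags.high_di, FOCAL, "high_di")
    both = intersect_loci(zhp_loci, di_loci)
    write_window_scores(outdir / "window_scores.tsv", scores)
    write_loci_tsv(outdir / "loci.tsv", zhp_loci + di_loci + both)

    def recovered(loci):
        hits = 0
        for ts, te in zip(truth_intervals.start, truth_intervals.end):
            if any(l.start < te and l.end > ts for l in loci):
                hits += 1
        return hits

    n_truth = len(truth_intervals)
    j = scores.pool_names.index(FOCAL)
    print(f"\n== {label} ==")
    print(f"windows: {frame.n_windows}; min ZHp({FOCAL}) = "
          f"{np.nanmin(scores.zhp[:, j]):.2f}; "
          f"di top-1% cutoff = {flags.di_cutoff:.2f}")
    print(f"flagged: {int(flags.low_zhp.sum())} low-ZHp, "
          f"{int(flags.high_di.sum())} high-di windows -> "
          f"{len(zhp_loci)} + {len(di_loci)} loci, {len(both)} overlapping")
    print(f"truth intervals recovered: dual-criterion {recovered(both)}/{n_truth}, "
          f"either criterion {recovered(zhp_loci + di_loci)}/{n_truth}")


def main() -> None:
    sim = ROOT / "sim"
    table = read_count_table(sim / "counts.tsv")
    chrom_lengths = read_chrom_lengths(sim / "chrom_lengths.tsv")
    truth = read_intervals_bed(sim / "truth_sweeps.bed")
    scan(table, chrom_lengths, truth, ROOT / "scan", "study genome: 10 sweeps (10% of 30 Mb)")

    # sparse-sweep contrast: one 300-kb sweep on the same genome size
    cfg = SimConfig(
        n_pools=8, chrom_lengths={"chr1": 30_000_000},
        sweeps=[Sweep("chr1", 14_850_000, 15_150_000, FOCAL, 0.95)],
        seed=43,
    )
    table2, truth2, _ = simulate_genome(cfg)
    scan(table2, cfg.chrom_lengths, truth2.intervals, ROOT / "scan_sparse",
         "sparse contrast: 1 sweep (1% of 30 Mb)")
    print("\nWith a dense sweep dose the sweeps contaminate the genome-wide "
          "mu/sigma of Hp, muting ZHp; with a sparse dose the same pipeline "
          "flags the sweep under both criteria.")


if __name__ == "__main__":
    main()
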