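"""Sliding-window skeleton over autosomes and SNP-to-window assignment.

Windows tile each autosome from coordinate 0 in fixed steps; the last
window on a chromosome is truncated at the chromosome length.  Sex
chromosomes (anything not listed as an autosome) produce no windows,
since they experience different effective population sizes and selective
pressures than autosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import SnpTable

DEFAULT_WINDOW_SIZE = 150_000
DEFAULT_STEP = 75_000


@dataclass
class WindowFrame:
    """Per-window coordinates (0-based half-open) plus SNP membership."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    window_size: int
    step: int
    chrom_lengths: dict[str, int]
    autosomes: list[str]
    snp_indices: list[np.ndarray] | None = None
    n_skipped_snps: int = 0
    n_snps: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if self.n_snps is None:
            if self.snp_indices is not None:
                self.n_snps = np.array([len(ix) for ix in self.snp_indices])
            else:
                self.n_snps = np.zeros(len(self.start), dtype=np.int64)

    @property
    def n_windows(self) -> int:
        return len(self.start)

    def membership_flat(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (window_id, snp_id) pairs for vectorised aggregation."""
        if self.snp_indices is None:
            raise ValueError("SNPs not assigned; call assign_snps first")
        win_ids = np.repeat(np.arange(self.n_windows), self.n_snps)
        snp_ids = (
            np.concatenate(self.snp_indices)
            if self.n_windows
            else np.array([], dtype=np.int64)
        )
        return win_ids, snp_ids.astype(np.int64)


def make_windows(
    chrom_lengths: dict[str, int],
    autosomes: Sequence[str],
    window_size: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_STEP,
) -> WindowFrame:
    """Build overlapping sliding windows over the listed autosomes.

    Consecutive windows on a chromosome start exactly ``step`` apart; a
    step larger than the window would leave unscanned gaps and raises.
    """
    if not (1 <= step <= window_size):
        raise ValueError(
            f"need 1 <= step <= window_size, got step={step}, window_size={window_size}"
        )
    unknown = [c for c in autosomes if c not in chrom_lengths]
    if unknown:
        raise ValueError(f"autosomes missing from chrom_lengths: {unknown}")
    chroms, starts, ends = [], [], []
    for c in autosomes:
        length = int(chrom_lengths[c])
        if length <= 0:
            raise ValueError(f"non-positive length for {c}")
        if length <= window_size:
            w_starts = np.array([0], dtype=np.int64)
        else:
            w_starts = np.arange(0, length, step, dtype=np.int64)
        w_ends = np.minimum(w_starts + window_size, length)
        chroms.extend([c] * len(w_starts))
        starts.append(w_starts)
        ends.append(w_ends)
    return WindowFrame(
        chrom=np.array(chroms, dtype=object),
        start=np.concatenate(starts) if starts else np.array([], dtype=np.int64),
        end=np.concatenate(ends) if ends else np.array([], dtype=np.int64),
        window_size=window_size,
        step=step,
        chrom_lengths=dict(chrom_lengths),
        autosomes=list(autosomes),
    )


def assign_snps(snps: SnpTable, frame: WindowFrame) -> WindowFrame:
    """Assign each SNP to every window containing it.

    A SNP at 1-based position ``pos`` belongs to window [start, end) iff
    ``start <= pos - 1 < end``.  SNPs on chromosomes without windows
    (non-autosomes or absent from the frame) are skipped and tallied in
    ``n_skipped_snps``.
    """
    w = frame.window_size
    s = frame.step
    per_window: list[list[int]] = [[] for _ in range(frame.n_windows)]
    # window offsets per chromosome for direct index arithmetic
    chrom_offset: dict[str, tuple[int, int]] = {}
    for c in frame.autosomes:
        on = np.flatnonzero(frame.chrom == c)
        if len(on):
            chrom_offset[c] = (int(on[0]), len(on))
    skipped = 0
    pos0_all = snps.pos - 1
    for c in np.unique(snps.chrom):
        sel = np.flatnonzero(snps.chrom == c)
        if c not in chrom_offset:
            skipped += len(sel)
            continue
        offset, n_win = chrom_offset[c]
        for i in sel:
            pos0 = int(pos0_all[i])
            if pos0 >= frame.chrom_lengths[c]:
                skipped += 1
                continue
            k_lo = max(0, -(-(pos0 - w + 1) // s))  # ceil((pos0 - w + 1)/s)
            k_hi = min(n_win - 1, pos0 // s)
            hit = False
            for k in range(k_lo, k_hi + 1):
                if frame.start[offset + k] <= pos0 < frame.end[offset + k]:
                    per_window[offset + k].append(int(i))
                    hit = True
            if not hit:
                skipped += 1
    indices = [np.array(sorted(ix), dtype=np.int64) for ix in per_window]
    return WindowFrame(
        chrom=frame.chrom,
        start=frame.start,
        end=frame.end,
        window_size=frame.window_size,
        step=frame.step,
        chrom_lengths=frame.chrom_lengths,
        autosomes=frame.autosomes,
        snp_indices=indices,
        n_skipped_snps=skipped,
        n_snps=np.array([len(ix) for ix in indices], dtype=np.int64),
    )
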