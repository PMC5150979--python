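"""Synthetic pool-seq generator with planted selective sweeps.

The model: every SNP has an ancestral allele frequency drawn uniformly
from a configurable range; each pool's frequency is then drawn from the
Balding–Nichols Beta distribution around the ancestral value with drift
parameter F (mean p, variance F·p(1−p)), which produces the among-breed
differentiation the di statistic measures.  Inside each planted sweep
interval the focal pool's frequency is pulled deterministically toward
the nearer fixation point by an intensity s ∈ [0, 1] — the
reduced-heterozygosity, elevated-differentiation signature of a
selective sweep, with exact control of effect size.  Read counts are
Poisson-depth binomial draws per pool, emulating pooled resequencing.

Defaults mirror a medium-coverage eight-breed pooled resequencing
design: 8 pools, mean depth 10×, ~one SNP per 1.5 kb (≈100 SNPs per
150-kb window), drift F = 0.1.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .io_formats import IntervalSet, SnpTable

_BASE_PAIRS = [
    ("A", "C"), ("A", "G"), ("A", "T"), ("C", "A"), ("C", "G"), ("C", "T"),
    ("G", "A"), ("G", "C"), ("G", "T"), ("T", "A"), ("T", "C"), ("T", "G"),
]


@dataclass
class Sweep:
    """A planted sweep: interval, focal pool, and intensity s ∈ [0, 1]."""

    chrom: str
    start: int
    end: int
    focal: str
    intensity: float


@dataclass
class SimConfig:
    """Simulator parameters; defaults are the package's study conditions."""

    n_pools: int = 8
    pool_names: list[str] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 30_000_000}
    )
    snp_density: float = 1.0 / 1500.0  # SNPs per bp
    drift_f: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.95)
    mean_depth: float = 10.0
    sweeps: list[Sweep] = field(default_factory=list)
    seed: int = 0
    emit_true_freqs: bool = False
    true_freq_scale: int = 10_000  # counts per pool when emitting exact freqs

    def __post_init__(self) -> None:
        if not self.pool_names:
            self.pool_names = [f"pool{i + 1}" for i in range(self.n_pools)]
        self.n_pools = len(self.pool_names)
        self.sweeps = [
            Sweep(**s) if isinstance(s, dict) else s for s in self.sweeps
        ]
        self.validate()

    def validate(self) -> None:
        if not 0 < self.drift_f < 1:
            raise ValueError(f"drift_f must be in (0, 1), got {self.drift_f}")
        lo, hi = self.maf_range
        if not 0 <= lo < hi <= 1:
            raise ValueError(f"invalid maf_range {self.maf_range}")
        if self.snp_density <= 0 or self.mean_depth <= 0:
            raise ValueError("snp_density and mean_depth must be positive")
        for sw in self.sweeps:
            if sw.chrom not in self.chrom_lengths:
                raise ValueError(f"sweep on unknown chromosome {sw.chrom!r}")
            if not 0 <= sw.start < sw.end <= self.chrom_lengths[sw.chrom]:
                raise ValueError(
                    f"sweep interval {sw.chrom}:{sw.start}-{sw.end} out of bounds"
                )
            if sw.focal not in self.pool_names:
                raise ValueError(f"sweep focal pool {sw.focal!r} not a pool")
            if not 0 <= sw.intensity <= 1:
                raise ValueError(f"sweep intensity {sw.intensity} outside [0, 1]")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["chrom_lengths"] = {k: int(v) for k, v in d["chrom_lengths"].items()}
        d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


@dataclass
class SweepTruth:
    """Ground-truth sweep intervals, exportable as BED."""

    intervals: IntervalSet
    sweeps: list[Sweep]


def balding_nichols_freq(p, f: float, rng: np.random.Generator) -> np.ndarray:
    """Draw population frequencies from Beta(p(1−F)/F, (1−p)(1−F)/F).

    Mean p, variance F·p(1−p).  Ancestral frequencies of exactly 0 or 1
    are returned unchanged (the Beta parameters degenerate there).
    """
    p = np.asarray(p, dtype=float)
    if not 0 < f < 1:
        raise ValueError(f"drift F must be in (0, 1), got {f}")
    scale = (1.0 - f) / f
    interior = (p > 0) & (p < 1)
    out = p.astype(float).copy()
    if interior.any():
        pi = p[interior]
        out[interior] = rng.beta(pi * scale, (1.0 - pi) * scale)
    return out if out.ndim else float(out)


def apply_sweep(p_focal, intensity: float) -> np.ndarray:
    """Pull frequencies toward the nearer fixation point.

    Returns (1−s)·p + s·round(p) with ties at 0.5 rounding toward 1;
    s = 1 fixes the allele outright, s = 0 is the identity.
    """
    p = np.asarray(p_focal, dtype=float)
    target = np.where(p >= 0.5, 1.0, 0.0)
    out = (1.0 - intensity) * p + intensity * target
    return out if out.ndim else float(out)


def sample_reads(
    p, mean_depth: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled read counts: depth ~ Poisson(mean_depth), alt ~ Binomial(d, p)."""
    p = np.asarray(p, dtype=float)
    d = rng.poisson(mean_depth, size=p.shape)
    alt = rng.binomial(d, p)
    return d - alt, alt


def simulate_genome(
    config: SimConfig,
) -> tuple[SnpTable, SweepTruth, np.ndarray]:
    """Generate a full synthetic SNP table plus sweep ground truth.

    SNP positions are placed uniformly at the configured density
    (Poisson-distributed count per chromosome).  Returns the SnpTable,
    the SweepTruth intervals, and the (n_snps, n_pools) matrix of true
    post-sweep frequencies.  With ``emit_true_freqs`` the counts are the
    exact frequencies scaled to ``true_freq_scale`` reads instead of
    sampled reads.  Deterministic given ``config.seed``.
    """
    config.validate()  # fail before any sampling
    rng = np.random.default_rng(config.seed)
    chroms_list, pos_list = [], []
    for c in sorted(config.chrom_lengths):
        length = config.chrom_lengths[c]
        n = rng.poisson(length * config.snp_density)
        pos0 = np.unique(rng.integers(0, length, size=n))
        while len(pos0) < n:  # top up collisions; keeps density exact-ish
            extra = rng.integers(0, length, size=n - len(pos0))
            pos0 = np.unique(np.concatenate([pos0, extra]))
        chroms_list.extend([c] * len(pos0))
        pos_list.append(pos0)
    chrom = np.array(chroms_list, dtype=object)
    pos = np.concatenate(pos_list) + 1  # 1-based
    n_snps = len(pos)

    pair_idx = rng.integers(0, len(_BASE_PAIRS), size=n_snps)
    ref = np.array([_BASE_PAIRS[i][0] for i in pair_idx], dtype=object)
    alt = np.array([_BASE_PAIRS[i][1] for i in pair_idx], dtype=object)

    lo, hi = config.maf_range
    p_anc = rng.uniform(lo, hi, size=n_snps)
    freqs = np.empty((n_snps, config.n_pools))
    for j in range(config.n_pools):
        freqs[:, j] = balding_nichols_freq(p_anc, config.drift_f, rng)
    for sw in config.sweeps:
        j = config.pool_names.index(sw.focal)
        m = (chrom == sw.chrom) & (pos - 1 >= sw.start) & (pos - 1 < sw.end)
        freqs[m, j] = apply_sweep(freqs[m, j], sw.intensity)

    if config.emit_true_freqs:
        scale = config.true_freq_scale
        alt_c = np.rint(freqs * scale).astype(np.int64)
        ref_c = scale - alt_c
    else:
        ref_c = np.empty((n_snps, config.n_pools), dtype=np.int64)
        alt_c = np.empty((n_snps, config.n_pools), dtype=np.int64)
        for j in range(config.n_pools):
            ref_c[:, j], alt_c[:, j] = sample_reads(
                freqs[:, j], config.mean_depth, rng
            )

    table = SnpTable(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        ref_counts=ref_c, alt_counts=alt_c,
        pool_names=list(config.pool_names),
    )
    if config.sweeps:
        truth_iv = IntervalSet(
            np.array([s.chrom for s in config.sweeps], dtype=object),
            np.array([s.start for s in config.sweeps], dtype=np.int64),
            np.array([s.end for s in config.sweeps], dtype=np.int64),
            np.array(
                [f"{s.focal}|s={s.intensity:g}" for s in config.sweeps],
                dtype=object,
            ),
        )
    else:
        truth_iv = IntervalSet.empty()
    return table, SweepTruth(intervals=truth_iv, sweeps=list(config.sweeps)), freqs


def default_sweep_positions(
    chrom: str,
    chrom_length: int,
    n_sweeps: int,
    sweep_length: int,
    focal: str,
    intensity: float,
) -> list[Sweep]:
    """Evenly spaced, non-overlapping sweep intervals along one chromosome."""
    if n_sweeps * sweep_length > chrom_length:
        raise ValueError("sweeps do not fit on the chromosome")
    starts = np.linspace(
        0, chrom_length - sweep_length, n_sweeps
    ).astype(int) if n_sweeps > 1 else np.array([(chrom_length - sweep_length) // 2])
    return [
        Sweep(chrom=chrom, start=int(s), end=int(s + sweep_length),
              focal=focal, intensity=intensity)
        for s in starts
    ]
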