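"""Window statistics for the selection scan: Hp, ZHp, FST and di.

Pooled heterozygosity for a window is computed from summed read counts of
the most (``ΣnMaj``) and least (``ΣnMin``) frequently observed allele at
each SNP in each pool::

    Hp = 2 * ΣnMaj * ΣnMin / (ΣnMaj + ΣnMin)**2

Hp is then Z-transformed per pool using the mean and population standard
deviation over all included windows (ZHp).  Between-pool differentiation
uses the Nei/Hudson HT−HS fixation index on pool read frequencies, with a
ratio-of-averages combination across the SNPs of a window, and the di
statistic sums, over all other pools j, the pairwise window FST_ij
standardized by that pair's genome-wide mean and standard deviation —
large di marks windows where the focal pool is unusually differentiated
from everything else at once.

Conventions: standard deviations are population (n-denominator)
throughout; windows with fewer than ``min_snps`` SNPs are excluded from
all means, standard deviations and downstream selection and carry NaN
scores; negative window FST values (estimator noise) are retained
unclamped so pair means stay unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .genome_windows import WindowFrame
from .io_formats import SnpTable

DEFAULT_MIN_SNPS = 10


@dataclass
class WindowScores:
    """All per-window scores for one scan.

    2-D arrays are (n_windows, n_pools) in ``pool_names`` order; pairwise
    quantities are keyed by sorted pool-name tuples; ``di`` is keyed by
    focal pool name.  NaN marks excluded or undefined entries.
    """

    frame: WindowFrame
    pool_names: list[str]
    sum_nmaj: np.ndarray
    sum_nmin: np.ndarray
    hp: np.ndarray
    zhp: np.ndarray
    mu_hp: np.ndarray
    sigma_hp: np.ndarray
    included: np.ndarray
    min_snps: int
    fst: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    fst_mean: dict[tuple[str, str], float] = field(default_factory=dict)
    fst_sd: dict[tuple[str, str], float] = field(default_factory=dict)
    di: dict[str, np.ndarray] = field(default_factory=dict)


def window_allele_sums(
    snps: SnpTable, frame: WindowFrame, pool: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window sums of major/minor allele read counts for one pool.

    Major/minor is oriented per SNP per pool from that pool's own read
    counts; zero-depth SNPs contribute (0, 0).
    """
    j = snps.pool_index(pool)
    win_ids, snp_ids = frame.membership_flat()
    maj = np.bincount(
        win_ids, weights=snps.maj_counts[snp_ids, j], minlength=frame.n_windows
    )
    mn = np.bincount(
        win_ids, weights=snps.min_counts[snp_ids, j], minlength=frame.n_windows
    )
    return maj.astype(np.int64), mn.astype(np.int64)


def pooled_heterozygosity(sum_nmaj, sum_nmin):
    """Hp = 2·ΣnMaj·ΣnMin/(ΣnMaj+ΣnMin)²; NaN where both sums are zero."""
    a = np.asarray(sum_nmaj, dtype=float)
    b = np.asarray(sum_nmin, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("allele-count sums must be non-negative")
    tot = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        hp = np.where(tot > 0, 2.0 * a * b / np.maximum(tot, 1) ** 2, np.nan)
    return hp if hp.ndim else float(hp)


def z_transform(values) -> np.ndarray:
    """Standardize to mean 0, population sd 1 over the defined entries.

    NaN entries (excluded/undefined windows) do not enter the mean or sd
    and stay NaN in the output.
    """
    v = np.asarray(values, dtype=float)
    defined = ~np.isnan(v)
    if defined.sum() < 2:
        raise ValueError("need at least 2 defined values to Z-transform")
    mu = v[defined].mean()
    sigma = v[defined].std(ddof=0)
    if sigma <= 1e-12 * max(1.0, abs(mu)):
        raise ValueError("degenerate heterozygosity distribution (sd = 0)")
    with np.errstate(invalid="ignore"):
        return (v - mu) / sigma


def snp_fst(p1, p2) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP HT−HS fixation-index components for two pools.

    Returns ``(HT - HS, HT)`` with HT = 2·p̄(1−p̄), HS = p1(1−p1)+p2(1−p2).
    SNPs with HT = 0 are uninformative and should be excluded from window
    sums (the window combiner does this).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    for p in (p1, p2):
        ok = np.isnan(p) | ((p >= 0) & (p <= 1))
        if not ok.all():
            raise ValueError("allele frequency outside [0, 1]")
    pbar = (p1 + p2) / 2.0
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = p1 * (1.0 - p1) + p2 * (1.0 - p2)
    return ht - hs, ht


def window_fst(numerators, denominators) -> float:
    """Ratio-of-averages FST over a window's informative SNPs.

    NaN components (zero-depth pools) and HT = 0 SNPs are dropped; NaN is
    returned when no informative SNP remains.
    """
    num = np.asarray(numerators, dtype=float)
    den = np.asarray(denominators, dtype=float)
    ok = ~np.isnan(num) & ~np.isnan(den) & (den > 0)
    if not ok.any():
        return float("nan")
    return float(num[ok].sum() / den[ok].sum())


def pairwise_window_fst(
    snps: SnpTable, frame: WindowFrame, pools: Sequence[str]
) -> dict[tuple[str, str], np.ndarray]:
    """Window FST series for every pool pair, NaN where undefined."""
    freqs = snps.alt_freqs()
    win_ids, snp_ids = frame.membership_flat()
    out: dict[tuple[str, str], np.ndarray] = {}
    for a, b in combinations(sorted(pools), 2):
        ia, ib = snps.pool_index(a), snps.pool_index(b)
        num, den = snp_fst(freqs[:, ia], freqs[:, ib])
        num_w = num[snp_ids]
        den_w = den[snp_ids]
        ok = ~np.isnan(num_w) & ~np.isnan(den_w) & (den_w > 0)
        sum_num = np.bincount(
            win_ids[ok], weights=num_w[ok], minlength=frame.n_windows
        )
        sum_den = np.bincount(
            win_ids[ok], weights=den_w[ok], minlength=frame.n_windows
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(sum_den > 0, sum_num / np.maximum(sum_den, 1e-300), np.nan)
        out[(a, b)] = fst
    return out


def di_statistic(
    fst: dict[tuple[str, str], np.ndarray],
    focal: str,
    included: np.ndarray,
) -> tuple[np.ndarray, dict[tuple[str, str], float], dict[tuple[str, str], float]]:
    """di for the focal pool: Σ_j (FST_fj − E[FST_fj]) / sd(FST_fj).

    E and sd are the mean and population sd of each pair's window FST over
    included windows with a defined value.  di is defined only for
    included windows where every pair involving the focal pool has a
    defined FST.  Returns (di, pair means, pair sds).
    """
    pairs = [k for k in fst if focal in k]
    if not pairs:
        raise ValueError(f"no FST pairs involve focal pool {focal!r}")
    n_win = len(included)
    di = np.zeros(n_win)
    defined = included.copy()
    means: dict[tuple[str, str], float] = {}
    sds: dict[tuple[str, str], float] = {}
    for pair in pairs:
        series = fst[pair]
        use = included & ~np.isnan(series)
        if use.sum() < 2:
            raise ValueError(f"fewer than 2 usable windows for pair {pair}")
        mu = float(series[use].mean())
        sd = float(series[use].std(ddof=0))
        if sd <= 1e-12 * max(1.0, abs(mu)):
            raise ValueError(f"degenerate FST distribution for pair {pair} (sd = 0)")
        means[pair] = mu
        sds[pair] = sd
        defined &= ~np.isnan(series)
        with np.errstate(invalid="ignore"):
            di = di + (series - mu) / sd
    di[~defined] = np.nan
    return di, means, sds


def score_windows(
    snps: SnpTable,
    frame: WindowFrame,
    pools: Sequence[str] | None = None,
    focal_pools: Sequence[str] | None = None,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> WindowScores:
    """Compute every window score: ΣnMaj/ΣnMin, Hp, ZHp, pair FST, di.

    ``pools`` defaults to all pools in the table; ``focal_pools`` (for di)
    defaults to ``pools``.  Deterministic: identical inputs give identical
    scores.
    """
    if frame.snp_indices is None:
        from .genome_windows import assign_snps

        frame = assign_snps(snps, frame)
    pool_names = list(pools) if pools is not None else list(snps.pool_names)
    focal_pools = list(focal_pools) if focal_pools is not None else pool_names
    n_win = frame.n_windows
    n_pool = len(pool_names)
    included = frame.n_snps >= min_snps

    sum_nmaj = np.zeros((n_win, n_pool), dtype=np.int64)
    sum_nmin = np.zeros((n_win, n_pool), dtype=np.int64)
    hp = np.full((n_win, n_pool), np.nan)
    zhp = np.full((n_win, n_pool), np.nan)
    mu_hp = np.full(n_pool, np.nan)
    sigma_hp = np.full(n_pool, np.nan)
    for j, p in enumerate(pool_names):
        sum_nmaj[:, j], sum_nmin[:, j] = window_allele_sums(snps, frame, p)
        hp_j = pooled_heterozygosity(sum_nmaj[:, j], sum_nmin[:, j])
        hp_j = np.where(included, hp_j, np.nan)
        hp[:, j] = hp_j
        zhp[:, j] = z_transform(hp_j)
        defined = ~np.isnan(hp_j)
        mu_hp[j] = hp_j[defined].mean()
        sigma_hp[j] = hp_j[defined].std(ddof=0)

    fst = pairwise_window_fst(snps, frame, pool_names)
    for pair, series in fst.items():
        fst[pair] = np.where(included, series, np.nan)

    di: dict[str, np.ndarray] = {}
    fst_mean: dict[tuple[str, str], float] = {}
    fst_sd: dict[tuple[str, str], float] = {}
    for p in focal_pools:
        di_p, means, sds = di_statistic(fst, p, included)
        di[p] = di_p
        fst_mean.update(means)
        fst_sd.update(sds)

    return WindowScores(
        frame=frame,
        pool_names=pool_names,
        sum_nmaj=sum_nmaj,
        sum_nmin=sum_nmin,
        hp=hp,
        zhp=zhp,
        mu_hp=mu_hp,
        sigma_hp=sigma_hp,
        included=included,
        min_snps=min_snps,
        fst=fst,
        fst_mean=fst_mean,
        fst_sd=fst_sd,
        di=di,
    )
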