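import numpy as np
import pytest

from poolscan import SnpTable


def make_table(records, pool_names):
    """Build a SnpTable from (chrom, pos, ref, alt, [(ref_c, alt_c), ...]) tuples."""
    chrom = np.array([r[0] for r in records], dtype=object)
    pos = np.array([r[1] for r in records], dtype=np.int64)
    ref = np.array([r[2] for r in records], dtype=object)
    alt = np.array([r[3] for r in records], dtype=object)
    ref_c = np.array([[c[0] for c in r[4]] for r in records], dtype=np.int64)
    alt_c = np.array([[c[1] for c in r[4]] for r in records], dtype=np.int64)
    n = len(records)
    return SnpTable(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        ref_counts=ref_c.reshape(n, len(pool_names)),
        alt_counts=alt_c.reshape(n, len(pool_names)),
        pool_names=list(pool_names),
    )


def random_table(rng, n_snps=50, n_pools=3, chrom="chr1", max_count=40):
    """Random sorted SnpTable on one chromosome."""
    pos = np.sort(rng.choice(np.arange(1, 10 * n_snps + 1), n_snps, replace=False))
    bases = np.array(list("ACGT"), dtype=object)
    ref_i = rng.integers(0, 4, n_snps)
    alt_i = (ref_i + rng.integers(1, 4, n_snps)) % 4
    pools = [f"p{i}" for i in range(n_pools)]
    return SnpTable(
        chrom=np.array([chrom] * n_snps, dtype=object),
        pos=pos,
        ref=bases[ref_i],
        alt=bases[alt_i],
        ref_counts=rng.integers(0, max_count, (n_snps, n_pools)),
        alt_counts=rng.integers(0, max_count, (n_snps, n_pools)),
        pool_names=pools,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
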