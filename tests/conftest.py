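import numpy as np
import pandas as pd
import pytest

from dmrwwe import GroupedCounts, SiteTable


@pytest.fixture
def small_table():
    df = pd.DataFrame({
        "chrom": ["chr1"] * 3 + ["chr2"],
        "pos": [100, 150, 200, 50],
        "strand": ["+", "+", "-", "+"],
        "meth": [3, 0, 5, 10],
        "coverage": [10, 20, 10, 15],
    })
    return SiteTable(sample_id="s1", data=df)


def random_site_table(rng, sample_id="s", n=30, chroms=("chr1", "chr2")):
    chrom = rng.choice(list(chroms), size=n)
    pos = np.zeros(n, dtype=int)
    used = set()
    for i in range(n):
        p = int(rng.integers(1, 5000))
        while (chrom[i], p) in used:
            p = int(rng.integers(1, 5000))
        used.add((chrom[i], p))
        pos[i] = p
    cov = rng.integers(0, 60, size=n)
    meth = (rng.random(n) * (cov + 1)).astype(int)
    meth = np.minimum(meth, cov)
    strand = rng.choice(["+", "-", "."], size=n)
    return SiteTable(sample_id=sample_id, data=pd.DataFrame({
        "chrom": chrom, "pos": pos, "strand": strand,
        "meth": meth, "coverage": cov}))


def make_grouped(pos, meth_a, cov_a, meth_b, cov_b, chrom="chr1"):
    pos = np.asarray(pos)
    return GroupedCounts(
        chrom=np.array([chrom] * len(pos), dtype=object), pos=pos,
        meth_a=np.asarray(meth_a), cov_a=np.asarray(cov_a),
        meth_b=np.asarray(meth_b), cov_b=np.asarray(cov_b))


def random_grouped(rng, n_sites=50, r_a=3, r_b=3, block=None,
                   cov_low=0, cov_high=60):
    """Random aligned counts; `block` = (start, end) site-index range where
    the two groups are pushed strongly apart."""
    gaps = rng.integers(1, 400, size=n_sites)
    pos = 100 + np.cumsum(gaps)
    cov_a = rng.integers(cov_low, cov_high, size=(n_sites, r_a))
    cov_b = rng.integers(cov_low, cov_high, size=(n_sites, r_b))
    mu = rng.random(n_sites)
    mu_a = mu.copy()
    mu_b = np.clip(mu + rng.normal(0, 0.1, size=n_sites), 0, 1)
    if block is not None:
        s, e = block
        mu_a[s:e + 1] = 0.1
        mu_b[s:e + 1] = 0.9
    meth_a = rng.binomial(cov_a, mu_a[:, None])
    meth_b = rng.binomial(cov_b, mu_b[:, None])
    return make_grouped(pos, meth_a, cov_a, meth_b, cov_b)
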