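"""The Weighted Welch Expansion (WWE) region caller.

A DMR is grown from position-sorted per-cytosine verdicts in a single
left-to-right pass per chromosome.  A site *qualifies* when

1. every replicate of both groups meets the minimum coverage,
2. the absolute difference of the coverage-weighted group means exceeds
   the minimum difference, and
3. the per-site two-sided p-value (weighted Welch, or Fisher's exact when
   a group has a single replicate) is at or below the threshold.

A candidate region opens at a qualifying site, whose sign of difference
fixes the region's direction.  It expands across subsequent sites while
qualifying sites keep the same direction and consecutive included sites
stay within ``max_gap`` nucleotides; up to ``max_similar`` consecutive
non-qualifying ("similar") sites are tolerated inside the expansion.  The
candidate terminates when the similar run grows too long, a qualifying
site of the opposite direction appears (immediately seeding a new
candidate), the gap is exceeded, or the chromosome ends; it then shrinks
back to its last qualifying site, so both boundaries are qualifying
cytosines.  Regions with at least ``min_cpn`` qualifying sites and at
least ``min_span`` nucleotides are emitted; each gets a region-level
p-value from the test applied to its coverage-aggregated per-replicate
counts, and Benjamini-Hochberg adjustment is applied across all regions
emitted in the run.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, replace, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import DMR, GroupedCounts
from .stats import (FISHER_EXACT, TestResult, WEIGHTED_WELCH, _welch_arrays,
                    bh_adjust, fisher_exact_test, site_p_value)


class EmptyRegionError(ValueError):
    """A region query containing no aligned site."""


@dataclass(frozen=True)
class DMRCriteria:
    """The seven user-tunable region-calling thresholds.

    Attributes
    ----------
    min_coverage : int
        Minimum read coverage required of *every* replicate in both groups
        at a qualifying site (default 10).
    min_diff : float
        Minimum absolute difference of the group coverage-weighted mean
        methylation levels, in percentage points (default 10).
    max_p : float
        Per-site two-sided p-value threshold (default 0.05).
    min_cpn : int
        Minimum number of qualifying CpN per emitted region (default 5).
    min_span : int
        Minimum genomic length of a region in nucleotides (default 0).
    max_gap : int
        Maximum distance in nucleotides between consecutive CpN included
        in a region (default 20000).
    max_similar : int
        Maximum run of consecutive non-qualifying CpN tolerated inside an
        expanding region (default 5).
    """

    min_coverage: int = 10
    min_diff: float = 10.0
    max_p: float = 0.05
    min_cpn: int = 5
    min_span: int = 0
    max_gap: int = 20_000
    max_similar: int = 5

    def __post_init__(self) -> None:
        if self.min_coverage < 0 or self.min_diff < 0 or self.min_span < 0 \
                or self.max_gap < 0 or self.max_similar < 0:
            raise ValueError("criteria thresholds must be >= 0")
        if not (0.0 < self.max_p <= 1.0):
            raise ValueError("max_p must lie in (0, 1]")
        if self.min_cpn < 1:
            raise ValueError("min_cpn must be >= 1")

    def replace(self, **kwargs) -> "DMRCriteria":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SiteVerdict:
    """Qualification outcome of one genomic site."""

    qualifies: bool
    failed_criteria: frozenset
    diff: float
    p: float

    def __post_init__(self) -> None:
        assert self.qualifies == (len(self.failed_criteria) == 0)


def _weighted_means(meth: np.ndarray, cov: np.ndarray) -> np.ndarray:
    total = cov.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, meth.sum(axis=1) / np.where(total > 0, total, 1),
                        np.nan)


def site_statistics(data: GroupedCounts) -> pd.DataFrame:
    """Per-site weighted means, difference and p-value for all sites.

    Uses the vectorised weighted Welch test when both groups have >= 2
    replicates; otherwise pools counts per group and runs Fisher's exact
    test site by site.
    """
    mean_a = _weighted_means(data.meth_a, data.cov_a)
    mean_b = _weighted_means(data.meth_b, data.cov_b)
    diff = mean_b - mean_a
    n = data.n_sites
    if min(data.r_a, data.r_b) >= 2:
        _, _, p = _welch_arrays(data.meth_a, data.cov_a, data.meth_b, data.cov_b)
        method = WEIGHTED_WELCH
    else:
        p = np.empty(n)
        ma = data.meth_a.sum(axis=1)
        ca = data.cov_a.sum(axis=1)
        mb = data.meth_b.sum(axis=1)
        cb = data.cov_b.sum(axis=1)
        for i in range(n):
            if ca[i] + cb[i] == 0:
                p[i] = np.nan
                continue
            p[i] = fisher_exact_test(int(ma[i]), int(ca[i] - ma[i]),
                                     int(mb[i]), int(cb[i] - mb[i])).p
        method = FISHER_EXACT
    return pd.DataFrame({
        "chrom": data.chrom, "pos": data.pos,
        "mean_a": mean_a, "mean_b": mean_b, "diff": diff, "p": p,
        "method": method,
    })


def site_verdicts(data: GroupedCounts, criteria: DMRCriteria) -> pd.DataFrame:
    """Vectorised per-site verdicts against criteria 1-3.

    Returns the :func:`site_statistics` frame plus boolean columns
    ``cov_ok``, ``diff_ok``, ``p_ok`` and ``qualifies``.
    """
    stats = site_statistics(data)
    cov_ok = ((data.cov_a >= criteria.min_coverage).all(axis=1)
              & (data.cov_b >= criteria.min_coverage).all(axis=1))
    with np.errstate(invalid="ignore"):
        diff_ok = np.abs(stats["diff"].to_numpy()) >= criteria.min_diff / 100.0
        p_ok = stats["p"].to_numpy() <= criteria.max_p
    diff_ok &= ~np.isnan(stats["diff"].to_numpy())
    p_ok &= ~np.isnan(stats["p"].to_numpy())
    stats["cov_ok"] = cov_ok
    stats["diff_ok"] = diff_ok
    stats["p_ok"] = p_ok
    stats["qualifies"] = cov_ok & diff_ok & p_ok
    return stats


def site_verdict(meth_a, cov_a, meth_b, cov_b,
                 criteria: DMRCriteria) -> SiteVerdict:
    """Verdict for a single site given per-replicate counts of each group."""
    ma = np.asarray(meth_a, dtype=np.int64)
    ca = np.asarray(cov_a, dtype=np.int64)
    mb = np.asarray(meth_b, dtype=np.int64)
    cb = np.asarray(cov_b, dtype=np.int64)
    data = GroupedCounts(chrom=np.array(["_"], dtype=object),
                         pos=np.array([1]),
                         meth_a=ma[None, :], cov_a=ca[None, :],
                         meth_b=mb[None, :], cov_b=cb[None, :])
    row = site_verdicts(data, criteria).iloc[0]
    failed = set()
    if not row["cov_ok"]:
        failed.add("coverage")
    if not row["diff_ok"]:
        failed.add("diff")
    if not row["p_ok"]:
        failed.add("p")
    return SiteVerdict(qualifies=bool(row["qualifies"]),
                       failed_criteria=frozenset(failed),
                       diff=float(row["diff"]), p=float(row["p"]))


def region_test(data: GroupedCounts, chrom: str, start: int, end: int):
    """Aggregate a region's counts per replicate and test the groups.

    Counts are summed over the region's aligned sites within each
    replicate; the group means come from the aggregated totals and the
    p-value from the same dispatch rule as the per-site test applied to
    the aggregated per-replicate counts.

    Returns ``(mean_a, mean_b, diff, p)``.
    """
    mask = (data.chrom == chrom) & (data.pos >= start) & (data.pos <= end)
    if not mask.any():
        raise EmptyRegionError(f"no aligned site in {chrom}:{start}-{end}")
    ma = data.meth_a[mask].sum(axis=0)
    ca = data.cov_a[mask].sum(axis=0)
    mb = data.meth_b[mask].sum(axis=0)
    cb = data.cov_b[mask].sum(axis=0)
    mean_a = float(ma.sum() / ca.sum()) if ca.sum() > 0 else float("nan")
    mean_b = float(mb.sum() / cb.sum()) if cb.sum() > 0 else float("nan")
    result = site_p_value(ma, ca, mb, cb)
    return mean_a, mean_b, mean_b - mean_a, result.p


def _scan_chromosome(pos: np.ndarray, qualifies: np.ndarray,
                     sign: np.ndarray, criteria: DMRCriteria):
    """Single left-to-right expansion pass; yields (first_idx, last_qual_idx)."""
    regions: list[tuple[int, int]] = []
    n = len(pos)
    first = last_qual = last_inc = -1
    direction = 0
    similar_run = 0

    def close():
        if first >= 0:
            regions.append((first, last_qual))

    i = 0
    while i < n:
        if first < 0:
            if qualifies[i]:
                first = last_qual = last_inc = i
                direction = sign[i]
                similar_run = 0
            i += 1
            continue
        gap = pos[i] - pos[last_inc]
        if gap > criteria.max_gap:
            close()
            first = -1
            continue  # revisit i as a fresh opener
        if qualifies[i] and sign[i] == direction:
            last_qual = last_inc = i
            similar_run = 0
        elif qualifies[i]:
            close()
            first = -1
            continue  # opposite direction seeds a new candidate at i
        else:
            similar_run += 1
            if similar_run > criteria.max_similar:
                close()
                first = -1
            else:
                last_inc = i
        i += 1
    close()
    return regions


def call_dmrs(data: GroupedCounts, criteria: DMRCriteria | None = None,
              verdicts: pd.DataFrame | None = None) -> list[DMR]:
    """Call DMRs on aligned two-group counts by weighted Welch expansion.

    Returns the emitted regions sorted by (chrom, start), non-overlapping,
    with region p-values and BH-adjusted q-values over the whole run.
    ``verdicts`` may be supplied to reuse a precomputed
    :func:`site_verdicts` frame (as in parameter sweeps).
    """
    if criteria is None:
        criteria = DMRCriteria()
    if verdicts is None:
        verdicts = site_verdicts(data, criteria)
    qual = verdicts["qualifies"].to_numpy()
    with np.errstate(invalid="ignore"):
        sign = np.sign(np.nan_to_num(verdicts["diff"].to_numpy()))

    raw: list[tuple[str, int, int, int]] = []  # chrom, first, last, n_cpn
    order = np.arange(data.n_sites)
    for chrom in pd.unique(data.chrom):
        idx = order[data.chrom == chrom]
        regions = _scan_chromosome(data.pos[idx], qual[idx], sign[idx], criteria)
        for f, l in regions:
            gi, gl = idx[f], idx[l]
            n_cpn = int(qual[gi:gl + 1].sum())
            span = int(data.pos[gl] - data.pos[gi] + 1)
            if n_cpn >= criteria.min_cpn and span >= criteria.min_span:
                raw.append((chrom, int(data.pos[gi]), int(data.pos[gl]), n_cpn))

    dmrs: list[DMR] = []
    for chrom, start, end, n_cpn in raw:
        mean_a, mean_b, diff, p = region_test(data, chrom, start, end)
        dmrs.append(DMR(chrom=chrom, start=start, end=end, n_cpn=n_cpn,
                        mean_a=mean_a, mean_b=mean_b, diff=diff, p=p))
    if dmrs:
        q = bh_adjust([d.p for d in dmrs])
        dmrs = [d.with_q(float(qi)) for d, qi in zip(dmrs, q)]
    return dmrs


def parameter_sweep(data: GroupedCounts,
                    grid: Mapping[str, Sequence] | None = None,
                    criteria: DMRCriteria | None = None) -> pd.DataFrame:
    """Count DMRs over the Cartesian product of criterion values.

    ``grid`` maps criterion names (fields of :class:`DMRCriteria`) to the
    values to try; unnamed criteria keep their (default or supplied)
    values.  An empty or missing grid yields the single defaults-only row.
    Returns a table with one row per combination and an ``n_dmrs`` column.
    """
    base = criteria if criteria is not None else DMRCriteria()
    grid = dict(grid or {})
    for key in grid:
        if key not in asdict(base):
            raise ValueError(f"unknown criterion {key!r}")
    names = list(grid)
    combos = list(itertools.product(*(grid[k] for k in names))) or [()]
    rows = []
    for combo in combos:
        crit = base.replace(**dict(zip(names, combo)))
        n = len(call_dmrs(data, crit))
        row = asdict(crit)
        row["n_dmrs"] = n
        rows.append(row)
    return pd.DataFrame(rows)


def plot_sweep(sweep: pd.DataFrame, parameter: str, ax=None):
    """Plot DMR count against one swept criterion (needs matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grouped = sweep.groupby(parameter)["n_dmrs"].mean()
    ax.plot(grouped.index, grouped.values, marker="o")
    ax.set_xlabel(parameter)
    ax.set_ylabel("number of DMRs")
    return ax
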