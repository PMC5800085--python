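"""Core in-memory containers shared across the package.

A :class:`SiteTable` holds one sample's per-cytosine methylated/total read
counts as a sorted pandas DataFrame; :class:`GroupedCounts` holds the
position-aligned count matrices for the two groups being compared; a
:class:`DMR` is one called region.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SITE_COLUMNS = ("chrom", "pos", "strand", "meth", "coverage")
VALID_STRANDS = frozenset({"+", "-", "."})


class MethylationDataError(ValueError):
    """Invalid methylation count data (counts, coordinates or ordering)."""


@dataclass
class SiteTable:
    """Per-sample cytosine counts, sorted by (chrom, pos), unique positions.

    Parameters
    ----------
    sample_id : str
        Identifier of the sample (used in outputs and error messages).
    data : pandas.DataFrame
        Columns ``chrom`` (str), ``pos`` (int, 1-based), ``strand``
        (one of ``+ - .``), ``meth`` (int), ``coverage`` (int).
    """

    sample_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in SITE_COLUMNS if c not in df.columns]
        if missing:
            raise MethylationDataError(
                f"{self.sample_id}: missing columns {missing}")
        df = df.loc[:, list(SITE_COLUMNS)].copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["meth"] = df["meth"].astype(np.int64)
        df["coverage"] = df["coverage"].astype(np.int64)
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        if (df["pos"] < 1).any():
            raise MethylationDataError(f"{self.sample_id}: positions must be >= 1")
        if (df["meth"] < 0).any() or (df["coverage"] < 0).any():
            raise MethylationDataError(f"{self.sample_id}: negative counts")
        if (df["meth"] > df["coverage"]).any():
            raise MethylationDataError(
                f"{self.sample_id}: meth count exceeds coverage")
        bad = ~df["strand"].isin(VALID_STRANDS)
        if bad.any():
            raise MethylationDataError(
                f"{self.sample_id}: invalid strand value {df.loc[bad, 'strand'].iloc[0]!r}")
        if df.duplicated(["chrom", "pos"]).any():
            dup = df.loc[df.duplicated(["chrom", "pos"]), ["chrom", "pos"]].iloc[0]
            raise MethylationDataError(
                f"{self.sample_id}: duplicate site {dup.chrom}:{dup.pos}")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def site_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.data[["chrom", "pos"]])

    def total_coverage(self) -> int:
        return int(self.data["coverage"].sum())

    def total_meth(self) -> int:
        return int(self.data["meth"].sum())

    def equals(self, other: "SiteTable") -> bool:
        return self.data.reset_index(drop=True).equals(
            other.data.reset_index(drop=True))


@dataclass
class GroupedCounts:
    """Position-aligned methylation count matrices for two replicate groups.

    All matrices have shape ``(n_sites, n_replicates)`` and share the same
    (chrom, pos) row order, sorted lexicographically by chromosome then
    position.
    """

    chrom: np.ndarray
    pos: np.ndarray
    meth_a: np.ndarray
    cov_a: np.ndarray
    meth_b: np.ndarray
    cov_b: np.ndarray
    samples_a: tuple[str, ...] = ()
    samples_b: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        for name in ("meth_a", "cov_a", "meth_b", "cov_b"):
            arr = np.atleast_2d(np.asarray(getattr(self, name), dtype=np.int64))
            setattr(self, name, arr)
        n = len(self.pos)
        for name in ("meth_a", "cov_a", "meth_b", "cov_b"):
            if getattr(self, name).shape[0] != n:
                raise MethylationDataError(
                    f"{name} has {getattr(self, name).shape[0]} rows, expected {n}")
        if self.meth_a.shape != self.cov_a.shape or self.meth_b.shape != self.cov_b.shape:
            raise MethylationDataError("meth/coverage matrix shapes differ")
        if self.r_a < 1 or self.r_b < 1:
            raise MethylationDataError("each group needs at least one replicate")
        if (self.meth_a > self.cov_a).any() or (self.meth_b > self.cov_b).any():
            raise MethylationDataError("meth count exceeds coverage")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def r_a(self) -> int:
        return self.meth_a.shape[1]

    @property
    def r_b(self) -> int:
        return self.meth_b.shape[1]

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c)
        return list(seen)


@dataclass(frozen=True)
class DMR:
    """One called differentially methylated region.

    Coordinates are 1-based inclusive; ``start`` and ``end`` are the first
    and last *qualifying* CpN of the region. ``diff = mean_b - mean_a`` is a
    fraction in [-1, 1]; ``direction`` is ``hyper`` when group B is more
    methylated than group A.
    """

    chrom: str
    start: int
    end: int
    n_cpn: int
    mean_a: float
    mean_b: float
    diff: float
    p: float
    q: float = float("nan")

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise MethylationDataError(f"DMR start {self.start} > end {self.end}")

    @property
    def direction(self) -> str:
        return "hyper" if self.diff > 0 else "hypo"

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def with_q(self, q: float) -> "DMR":
        return replace(self, q=q)


@dataclass(frozen=True)
class GeneInterval:
    """A gene (or any named feature) interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise MethylationDataError(
                f"gene {self.name}: start {self.start} > end {self.end}")


def dmrs_to_frame(dmrs: Sequence[DMR]) -> pd.DataFrame:
    """Tabulate a DMR list (one row per region)."""
    return pd.DataFrame(
        {
            "chrom": [d.chrom for d in dmrs],
            "start": [d.start for d in dmrs],
            "end": [d.end for d in dmrs],
            "n_cpn": [d.n_cpn for d in dmrs],
            "mean_a": [d.mean_a for d in dmrs],
            "mean_b": [d.mean_b for d in dmrs],
            "diff": [d.diff for d in dmrs],
            "p": [d.p for d in dmrs],
            "q": [d.q for d in dmrs],
            "direction": [d.direction for d in dmrs],
        }
    )
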