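"""Interval-level evaluation of predicted DMRs against truth intervals.

Implements the directional "DMR overlay" (percent of a query interval's
nucleotides covered by a reference set — asymmetric, unlike a Jaccard
index), overlap-based TP/FP/FN confusion counts, and precision / recall /
F1.  All intervals are 1-based inclusive; lengths are end - start + 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


@dataclass(frozen=True)
class IntervalSet:
    """A sorted, within-set non-overlapping set of genomic intervals."""

    intervals: tuple[tuple[str, int, int], ...]

    def __init__(self, intervals: Iterable[Sequence]):
        ivs = sorted((str(c), int(s), int(e)) for c, s, e in intervals)
        for c, s, e in ivs:
            if s > e:
                raise ValueError(f"interval {c}:{s}-{e} has start > end")
        for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
            if c1 == c2 and s2 <= e1:
                raise ValueError(
                    f"intervals {c1}:{s1}-{e1} and {c2}:{s2}-{e2} overlap")
        object.__setattr__(self, "intervals", tuple(ivs))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees (half-open: end + 1)."""
        out: dict[str, IntervalTree] = {}
        for c, s, e in self.intervals:
            out.setdefault(c, IntervalTree()).addi(s, e + 1)
        return out

    @classmethod
    def from_dmrs(cls, dmrs) -> "IntervalSet":
        return cls((d.chrom, d.start, d.end) for d in dmrs)

    @classmethod
    def from_bed(cls, path) -> "IntervalSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t") if "\t" in line else line.split()
                rows.append((f[0], int(f[1]) + 1, int(f[2])))
        return cls(rows)


@dataclass(frozen=True)
class ConfusionCounts:
    """Overlap-based interval confusion counts."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def dmr_overlay(query: IntervalSet, reference: IntervalSet) -> np.ndarray:
    """Percent of each query interval covered by the reference set.

    For each query interval, 100 x (nucleotides shared with any reference
    interval) / (query length).  Directional: swapping the arguments gives
    a different quantity.
    """
    trees = reference.trees()
    out = np.zeros(len(query))
    for i, (c, s, e) in enumerate(query):
        length = e - s + 1
        covered = 0
        for hit in trees.get(c, IntervalTree()).overlap(s, e + 1):
            covered += min(hit.end - 1, e) - max(hit.begin, s) + 1
        out[i] = 100.0 * covered / length
    return out


def confusion_counts(predicted: IntervalSet,
                     benchmark: IntervalSet) -> ConfusionCounts:
    """TP/FP/FN from >= 1-nucleotide overlap.

    A predicted interval overlapping at least one benchmark interval is a
    TP, otherwise an FP; a benchmark interval overlapped by no predicted
    interval is an FN.
    """
    btrees = benchmark.trees()
    ptrees = predicted.trees()
    tp = sum(1 for c, s, e in predicted
             if btrees.get(c) and btrees[c].overlaps(s, e + 1))
    fn = sum(1 for c, s, e in benchmark
             if not (ptrees.get(c) and ptrees[c].overlaps(s, e + 1)))
    return ConfusionCounts(tp=tp, fp=len(predicted) - tp, fn=fn)


def precision_recall_f1(counts: ConfusionCounts):
    """Precision TP/(TP+FP), recall TP/(TP+FN), and their harmonic mean.

    A 0/0 ratio is returned as ``nan``; F1 is 0 when either defined
    component is 0.
    """
    precision = counts.tp / (counts.tp + counts.fp) \
        if counts.tp + counts.fp > 0 else float("nan")
    recall = counts.tp / (counts.tp + counts.fn) \
        if counts.tp + counts.fn > 0 else float("nan")
    if np.isnan(precision) or np.isnan(recall):
        f1 = float("nan")
    elif precision == 0.0 or recall == 0.0:
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return precision, recall, f1


@dataclass(frozen=True)
class BenchmarkReport:
    """Bundle of confusion counts, metrics and both overlay directions."""

    counts: ConfusionCounts
    precision: float
    recall: float
    f1: float
    overlay_pred_vs_truth: np.ndarray = field(repr=False)
    overlay_truth_vs_pred: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        ov_p = self.overlay_pred_vs_truth
        ov_t = self.overlay_truth_vs_pred
        return pd.DataFrame({
            "metric": ["tp", "fp", "fn", "precision", "recall", "f1",
                       "mean_overlay_pred_vs_truth",
                       "mean_overlay_truth_vs_pred"],
            "value": [self.counts.tp, self.counts.fp, self.counts.fn,
                      self.precision, self.recall, self.f1,
                      float(np.mean(ov_p)) if len(ov_p) else float("nan"),
                      float(np.mean(ov_t)) if len(ov_t) else float("nan")],
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def evaluate(predicted: IntervalSet, benchmark: IntervalSet) -> BenchmarkReport:
    """Full report: counts, precision/recall/F1, both overlay directions."""
    counts = confusion_counts(predicted, benchmark)
    precision, recall, f1 = precision_recall_f1(counts)
    return BenchmarkReport(
        counts=counts, precision=precision, recall=recall, f1=f1,
        overlay_pred_vs_truth=dmr_overlay(predicted, benchmark),
        overlay_truth_vs_pred=dmr_overlay(benchmark, predicted),
    )
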